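"""Independent brute-force oracles used by the tests."""

import numpy as np
from scipy import ndimage
from skimage.measure import euler_number

_S26 = np.ones((3, 3, 3))


def _audit(block: np.ndarray):
    pad = np.pad(block, 1)
    _, n_fg = ndimage.label(pad, structure=_S26)
    _, n_bg = ndimage.label(~pad)
    return n_fg, n_bg, euler_number(pad, connectivity=3)


def simple_point_oracle(cfg: np.ndarray) -> bool:
    """Brute-force simpleness: flipping the centre of the (padded) 3x3x3
    block must leave foreground 26-components, background 6-components
    and the Euler number unchanged — i.e. all Betti numbers of both
    phases are preserved."""
    a = cfg.astype(bool).copy()
    b = a.copy()
    a[1, 1, 1] = False
    b[1, 1, 1] = True
    return _audit(a) == _audit(b)
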