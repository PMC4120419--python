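"""Small internal helpers."""

from __future__ import annotations

import numpy as np


def fast_copy(arr: np.ndarray) -> np.ndarray:
    """Copy via empty_like + copyto.

    Equivalent to ``arr.copy()`` but routed through the ufunc machinery,
    which streams large blocks much faster on some platforms.
    """
    out = np.empty_like(arr)
    np.copyto(out, arr)
    return out
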