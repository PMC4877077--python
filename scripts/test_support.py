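"""Independent reference computations used by the acceptance script."""

import numpy as np


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg adjusted p-values (step-up, running min)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return np.minimum(adjusted, 1.0)
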