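"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["total_variation"]


def total_variation(p, q) -> float:
    """Total variation distance 0.5 * sum |p - q| between two probability
    arrays; shorter arrays are zero-padded so supports need not match."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    n = max(p.size, q.size)
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: p.size] = p
    qq[: q.size] = q
    return 0.5 * float(np.abs(pp - qq).sum())
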