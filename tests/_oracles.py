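"""Independent reference implementations used only by the tests.

These deliberately use different algorithms from the package: the torsion
oracle projects bond vectors onto the plane normal to the central bond
(rather than the normal-vector atan2 route), and the run-scanner oracle
enumerates every (start, length) window and checks alternation and
maximality explicitly instead of sweeping.
"""

from __future__ import annotations

import numpy as np


def torsion_oracle(p1, p2, p3, p4) -> float:
    """Projection-based IUPAC torsion in degrees, range [-180, 180)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_close(a: float, b: float, tol: float) -> bool:
    """Circular closeness of two angles in degrees."""
    d = abs((a - b + 180.0) % 360.0 - 180.0)
    return d <= tol


def brute_force_runs(state_string: str, min_len: int) -> list[tuple[int, int]]:
    """All maximal alternating R/L windows of length >= min_len.

    A window [s, s+l) is *valid* when every character is R or L and adjacent
    characters differ; it is *maximal* when neither one-character extension
    is valid.  Returns (start, length) pairs sorted by start.
    """
    n = len(state_string)

    def valid(s: int, l: int) -> bool:
        if s < 0 or s + l > n:
            return False
        w = state_string[s : s + l]
        if any(c not in "RL" for c in w):
            return False
        return all(a != b for a, b in zip(w, w[1:]))

    out = []
    for s in range(n):
        for l in range(min_len, n - s + 1):
            if valid(s, l) and not valid(s - 1, l + 1) and not valid(s, l + 1):
                out.append((s, l))
    return sorted(out)
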