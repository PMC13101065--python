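import numpy as np
import pytest

from qpmorph import PhantomSpec, generate_phantom_cell
from qpmorph.phase import wrap_phase


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-size star phantom with truth mask and truth features."""
    return generate_phantom_cell(PhantomSpec(seed=1))


def brute_force_residues(phase: np.ndarray):
    """Independent O(HW) loop-sum residue oracle (explicit Python loops)."""
    pos, neg = [], []
    H, W = phase.shape
    for r in range(H - 1):
        for c in range(W - 1):
            s = (
                wrap_phase(phase[r, c + 1] - phase[r, c])
                + wrap_phase(phase[r + 1, c + 1] - phase[r, c + 1])
                - wrap_phase(phase[r + 1, c + 1] - phase[r + 1, c])
                - wrap_phase(phase[r + 1, c] - phase[r, c])
            )
            k = round(float(s) / (2 * np.pi))
            if k > 0:
                pos.append((r, c))
            elif k < 0:
                neg.append((r, c))
    return pos, neg


def convex_hull_area_monotone_chain(points: np.ndarray) -> float:
    """Brute-force convex hull area via Andrew's monotone chain (oracle)."""
    pts = sorted(map(tuple, points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0
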