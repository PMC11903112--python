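import numpy as np
import pytest


def random_star_polygon(rng, n_vertices=12, r_lo=0.5, r_hi=2.0):
    """Random simple (star-shaped) polygon: sorted angles, random radii."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # guard against duplicate angles producing zero-length edges
    angles += np.linspace(0, 1e-6, n_vertices)
    radii = rng.uniform(r_lo, r_hi, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_polygons(rng):
    return [random_star_polygon(rng, int(rng.integers(5, 40))) for _ in range(50)]


# --- independent oracles -------------------------------------------------

def brute_force_max_feret(vertices):
    """All-pairs distance over the original ring vertices."""
    v = np.asarray(vertices, float)
    d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
    return float(d.max())


def sweep_min_feret(vertices, n_angles=3600):
    """Minimum projected width over a dense sweep of directions."""
    v = np.asarray(vertices, float)
    th = np.linspace(0, np.pi, n_angles, endpoint=False)
    dirs = np.column_stack([np.cos(th), np.sin(th)])
    proj = v @ dirs.T  # (n_pts, n_angles)
    return float((proj.max(axis=0) - proj.min(axis=0)).min())


def brute_force_hull_vertices(points):
    """O(n^3) half-plane test: the set of extreme points."""
    p = np.asarray(points, float)
    n = len(p)
    extreme = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = p[j] - p[i]
            cross = d[0] * (p[:, 1] - p[i, 1]) - d[1] * (p[:, 0] - p[i, 0])
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(cross[mask] > 0) or np.all(cross[mask] < 0):
                extreme.add(i)
                extreme.add(j)
    return {tuple(p[i]) for i in extreme}


def brute_force_auc(scores, labels):
    """Pairwise concordance count (ties counted 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
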