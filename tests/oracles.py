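"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (O(n³) hulls, manual ranks, manual
quartiles, spherical-excess polygon areas) and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# planar convex hull by exhaustive extreme-edge check
# ---------------------------------------------------------------------------

def brute_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Hull vertices in counter-clockwise order, via O(n³) edge testing.

    An ordered pair (i, j) is a hull edge iff every other point lies
    left of or on the directed line i→j and no point lies beyond j on it.
    Degenerate (all-collinear) inputs return the two extreme points.
    """
    pts = np.unique(points, axis=0)
    n = len(pts)
    if n <= 2:
        return pts
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                cross = d[0] * (pts[k][1] - pts[i][1]) - d[1] * (pts[k][0] - pts[i][0])
                if cross < -1e-12:
                    ok = False
                    break
                if abs(cross) <= 1e-12:
                    # collinear: j must be the farthest point on the ray
                    t_k = np.dot(pts[k] - pts[i], d)
                    if t_k > np.dot(d, d) + 1e-12:
                        ok = False
                        break
            if ok:
                edges[i] = j
    if not edges:                      # fully collinear
        proj = pts @ (pts[-1] - pts[0])
        return pts[[int(np.argmin(proj)), int(np.argmax(proj))]]
    start = next(iter(edges))
    order = [start]
    cur = edges[start]
    while cur != start and len(order) <= n:
        order.append(cur)
        cur = edges[cur]
    return pts[order]


def shoelace_area(vertices: np.ndarray) -> float:
    if len(vertices) < 3:
        return 0.0
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def brute_hull_area(points: np.ndarray) -> float:
    return shoelace_area(brute_hull_vertices(points))


# ---------------------------------------------------------------------------
# spherical (geodesic) polygon area via l'Huilier's theorem
# ---------------------------------------------------------------------------

def _unit_vec(lat: float, lon: float) -> np.ndarray:
    la, lo = math.radians(lat), math.radians(lon)
    return np.array([math.cos(la) * math.cos(lo),
                     math.cos(la) * math.sin(lo),
                     math.sin(la)])


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    return math.atan2(float(np.linalg.norm(np.cross(u, v))), float(np.dot(u, v)))


def _triangle_excess(a: float, b: float, c: float) -> float:
    s = 0.5 * (a + b + c)
    t = (math.tan(s / 2) * math.tan((s - a) / 2)
         * math.tan((s - b) / 2) * math.tan((s - c) / 2))
    return 4.0 * math.atan(math.sqrt(max(t, 0.0)))


def spherical_polygon_area_km2(lats, lons, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area of a convex geodesic polygon given its ordered vertices."""
    verts = [_unit_vec(la, lo) for la, lo in zip(lats, lons)]
    if len(verts) < 3:
        return 0.0
    total = 0.0
    v0 = verts[0]
    for u, v in zip(verts[1:-1], verts[2:]):
        total += _triangle_excess(_angle(v0, u), _angle(u, v), _angle(v, v0))
    return total * radius_km ** 2


def haversine_closed_form_km(lat1, lon1, lat2, lon2) -> float:
    """Central-angle distance from 3D unit vectors (independent formula)."""
    return EARTH_RADIUS_KM * _angle(_unit_vec(lat1, lon1), _unit_vec(lat2, lon2))


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks for ties, built directly from sorting."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    xs = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks."""
    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------
# quartiles, fences, regression diagnostics
# ---------------------------------------------------------------------------

def quartile_type7(x: np.ndarray, p: float) -> float:
    xs = np.sort(np.asarray(x, float))
    h = (len(xs) - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def tukey_fences_oracle(x: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    q1, q3 = quartile_type7(x, 0.25), quartile_type7(x, 0.75)
    return q1 - k * (q3 - q1), q3 + k * (q3 - q1)


def vif_oracle(x: np.ndarray) -> np.ndarray:
    """VIF from the inverse of the sample correlation matrix diagonal."""
    xc = x - x.mean(axis=0)
    r = np.corrcoef(xc, rowvar=False)
    return np.diag(np.linalg.inv(r)).copy()


def adjusted_r2_oracle(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# reference stepwise selector (statsmodels-based, shares no code)
# ---------------------------------------------------------------------------

def stepwise_reference(y: np.ndarray, x: np.ndarray,
                       p_enter: float = 0.05, p_remove: float = 0.10) -> list[int]:
    """Forward/backward selection on column indices using statsmodels OLS."""
    import statsmodels.api as sm

    included: list[int] = []
    excluded = list(range(x.shape[1]))
    while True:
        changed = False
        best, best_p = None, np.inf
        for j in excluded:
            cols = included + [j]
            fit = sm.OLS(y, sm.add_constant(x[:, cols])).fit()
            pv = fit.pvalues[-1]
            if pv < best_p:
                best, best_p = j, pv
        if best is not None and best_p < p_enter:
            included.append(best)
            excluded.remove(best)
            changed = True
        while included:
            fit = sm.OLS(y, sm.add_constant(x[:, included])).fit()
            pv = fit.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                excluded.append(included.pop(worst))
                changed = True
            else:
                break
        if not changed:
            return included
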