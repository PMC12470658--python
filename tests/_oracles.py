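"""Independent exhaustive-loop and closed-form oracles for the test suite.

Everything here is deliberately naive (pure-Python loops, direct formulas,
full enumeration) and shares no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import math


def cell_center(geometry, j: int, i: int) -> tuple[float, float]:
    dx = geometry.extent_fast_mm / geometry.n_fast
    dy = geometry.extent_slow_mm / geometry.n_slow
    x = (i + 0.5) * dx - geometry.extent_fast_mm / 2
    y = (j + 0.5) * dy - geometry.extent_slow_mm / 2
    return x, y


def zone_mask_loop(geometry, radius_mm: float) -> list[list[bool]]:
    fx, fy = geometry.fovea_xy_mm
    out = []
    for j in range(geometry.n_slow):
        row = []
        for i in range(geometry.n_fast):
            x, y = cell_center(geometry, j, i)
            row.append(math.hypot(x - fx, y - fy) <= radius_mm)
        out.append(row)
    return out


def thickness_loop(boundaries) -> list[list[float]]:
    n_slow, n_fast = boundaries.shape
    out = []
    for j in range(n_slow):
        row = []
        for i in range(n_fast):
            row.append(max(boundaries.rpe_um[j, i] - boundaries.ez_um[j, i], 0.0))
        out.append(row)
    return out


def partial_attenuation_loop(ezmap, threshold_um: float = 20.0) -> float:
    count = total = 0
    for j in range(ezmap.geometry.n_slow):
        for i in range(ezmap.geometry.n_fast):
            if ezmap.valid[j, i]:
                total += 1
                if ezmap.thickness_um[j, i] <= threshold_um:
                    count += 1
    return 100.0 * count / total


def zone_mean_loop(ezmap, radius_mm: float) -> float:
    mask = zone_mask_loop(ezmap.geometry, radius_mm)
    acc = n = 0
    for j in range(ezmap.geometry.n_slow):
        for i in range(ezmap.geometry.n_fast):
            if mask[j][i] and ezmap.valid[j, i]:
                acc += ezmap.thickness_um[j, i]
                n += 1
    return acc / n


def zone_volume_loop(ezmap, radius_mm: float | None) -> float:
    """Volume over a disc, or the whole cube when radius is None."""
    geom = ezmap.geometry
    mask = (zone_mask_loop(geom, radius_mm) if radius_mm is not None
            else [[True] * geom.n_fast for _ in range(geom.n_slow)])
    cell = (geom.extent_fast_mm / geom.n_fast) * (geom.extent_slow_mm / geom.n_slow)
    acc = 0.0
    for j in range(geom.n_slow):
        for i in range(geom.n_fast):
            if mask[j][i] and ezmap.valid[j, i]:
                acc += ezmap.thickness_um[j, i] * 1e-3 * cell
    return acc


def bilinear_loop(ezmap, x_t: float, y_t: float) -> float:
    """Bilinear interpolation over valid cell centers, naive search."""
    geom = ezmap.geometry
    xs = [cell_center(geom, 0, i)[0] for i in range(geom.n_fast)]
    ys = [cell_center(geom, j, 0)[1] for j in range(geom.n_slow)]
    x_t = min(max(x_t, xs[0]), xs[-1])
    y_t = min(max(y_t, ys[0]), ys[-1])
    i1 = next((i for i, x in enumerate(xs) if x > x_t), len(xs) - 1)
    j1 = next((j for j, y in enumerate(ys) if y > y_t), len(ys) - 1)
    i0, j0 = max(i1 - 1, 0), max(j1 - 1, 0)
    tx = 0.0 if i1 == i0 else (x_t - xs[i0]) / (xs[i1] - xs[i0])
    ty = 0.0 if j1 == j0 else (y_t - ys[j0]) / (ys[j1] - ys[j0])
    pts = [((j0, i0), (1 - tx) * (1 - ty)), ((j0, i1), tx * (1 - ty)),
           ((j1, i0), (1 - tx) * ty), ((j1, i1), tx * ty)]
    num = den = 0.0
    for (j, i), w in pts:
        if ezmap.valid[j, i] and w > 0:
            num += w * ezmap.thickness_um[j, i]
            den += w
    return num / den


# -- statistics --------------------------------------------------------------


def paired_t_closed_form(x1, x2) -> tuple[float, float, float]:
    """(mean difference, sd of differences, t) by the direct formula."""
    d = [b - a for a, b in zip(x1, x2)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, mean / (sd / math.sqrt(n))


def welch_t_closed_form(x, y) -> tuple[float, float]:
    """(t statistic, Welch-Satterthwaite df) by the direct formula."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> float:
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def chi2_stat_loop(table) -> float:
    """Pearson chi-square statistic, no continuity correction."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    rsum = [sum(r) for r in table]
    csum = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            e = rsum[i] * csum[j] / total
            stat += (table[i][j] - e) ** 2 / e
    return stat


def kappa_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa for the 2x2 agreement table [[a, b], [c, d]]."""
    n = a + b + c + d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    return (p_o - p_e) / (1 - p_e)
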