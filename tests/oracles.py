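"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration (pure-Python loops,
exact-fraction arithmetic where feasible) and stays deliberately
independent of the package implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, log2, sqrt

import numpy as np

# --------------------------------------------------------------- texture

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def glcm_matrix_bruteforce(disc, offset, n_levels):
    """Symmetric co-occurrence counts by enumerating every voxel pair."""
    P = np.zeros((n_levels, n_levels))
    nx, ny, nz = disc.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = disc[x, y, z]
                if a == 0:
                    continue
                wx, wy, wz = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= wx < nx and 0 <= wy < ny and 0 <= wz < nz):
                    continue
                b = disc[wx, wy, wz]
                if b == 0:
                    continue
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    total = P.sum()
    return P / total if total else P


def glcm_features_bruteforce(disc, n_levels):
    per_dir = []
    for d in DIRS_13:
        P = glcm_matrix_bruteforce(disc, d, n_levels)
        if P.sum() == 0:
            continue
        L = n_levels
        mu = sum((i + 1) * P[i, j] for i in range(L) for j in range(L))
        sig2 = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
        f = {
            "Contrast": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
            "Dissimilarity": sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L)),
            "Homogeneity": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
            "Energy": sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
            "JointEntropy": -sum(
                P[i, j] * log2(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0
            ),
            "Correlation": (
                sum(
                    (i + 1 - mu) * (j + 1 - mu) * P[i, j]
                    for i in range(L)
                    for j in range(L)
                )
                / sig2
                if sig2 > 1e-12
                else 1.0
            ),
            "ClusterShade": sum(
                (i + j + 2 - 2 * mu) ** 3 * P[i, j] for i in range(L) for j in range(L)
            ),
            "ClusterProminence": sum(
                (i + j + 2 - 2 * mu) ** 4 * P[i, j] for i in range(L) for j in range(L)
            ),
        }
        per_dir.append(f)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def runs_bruteforce(disc, d):
    """Maximal same-level runs along one direction by walking every line."""
    shape = disc.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = disc[x, y, z]
                if g == 0:
                    continue
                px, py, pz = x - d[0], y - d[1], z - d[2]
                if (
                    0 <= px < shape[0]
                    and 0 <= py < shape[1]
                    and 0 <= pz < shape[2]
                    and disc[px, py, pz] == g
                ):
                    continue  # not a run start
                length = 0
                cx, cy, cz = x, y, z
                while (
                    0 <= cx < shape[0]
                    and 0 <= cy < shape[1]
                    and 0 <= cz < shape[2]
                    and disc[cx, cy, cz] == g
                ):
                    length += 1
                    cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                runs.append((int(g), length))
    return runs


def glrlm_features_bruteforce(disc):
    n_vox = int((disc > 0).sum())
    per_dir = []
    for d in DIRS_13:
        runs = runs_bruteforce(disc, d)
        nr = len(runs)
        by_g: dict[int, int] = {}
        by_l: dict[int, int] = {}
        for g, ln in runs:
            by_g[g] = by_g.get(g, 0) + 1
            by_l[ln] = by_l.get(ln, 0) + 1
        per_dir.append(
            {
                "ShortRunEmphasis": sum(1.0 / ln**2 for _, ln in runs) / nr,
                "LongRunEmphasis": sum(ln**2 for _, ln in runs) / nr,
                "GrayLevelNonUniformity": sum(c**2 for c in by_g.values()) / nr,
                "RunLengthNonUniformity": sum(c**2 for c in by_l.values()) / nr,
                "RunPercentage": nr / n_vox,
                "LowGrayLevelRunEmphasis": sum(1.0 / g**2 for g, _ in runs) / nr,
                "HighGrayLevelRunEmphasis": sum(g**2 for g, _ in runs) / nr,
            }
        )
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def zones_bruteforce(disc):
    """26-connected equal-level zones by breadth-first flood fill."""
    shape = disc.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    neigh = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if disc[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = disc[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        wx, wy, wz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= wx < shape[0]
                            and 0 <= wy < shape[1]
                            and 0 <= wz < shape[2]
                            and not seen[wx, wy, wz]
                            and disc[wx, wy, wz] == g
                        ):
                            seen[wx, wy, wz] = True
                            stack.append((wx, wy, wz))
                zones.append((int(g), size))
    return zones


def glszm_features_bruteforce(disc):
    zones = zones_bruteforce(disc)
    n_vox = int((disc > 0).sum())
    nz = len(zones)
    by_g: dict[int, int] = {}
    by_s: dict[int, int] = {}
    for g, s in zones:
        by_g[g] = by_g.get(g, 0) + 1
        by_s[s] = by_s.get(s, 0) + 1
    return {
        "SmallAreaEmphasis": sum(1.0 / s**2 for _, s in zones) / nz,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in by_g.values()) / nz,
        "SizeZoneNonUniformity": sum(c**2 for c in by_s.values()) / nz,
        "ZonePercentage": nz / n_vox,
        "LowGrayLevelZoneEmphasis": sum(1.0 / g**2 for g, _ in zones) / nz,
        "HighGrayLevelZoneEmphasis": sum(g**2 for g, _ in zones) / nz,
    }


# --------------------------------------------------------------- agreement

def icc21_bruteforce(table):
    """ICC(2,1) from explicit sum-of-squares loops."""
    x = [[float(v) for v in row] for row in table]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0
    return (msr - mse) / denom


# --------------------------------------------------------------- ranking / tests

def auc_paircount(scores, labels):
    """Mann-Whitney concordance: concordant pairs (+0.5 per tie) / all pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def youden_bruteforce(scores, labels):
    """Exhaustive threshold scan; returns (cutoff, J). Rule: high iff >= cutoff."""
    uniq = sorted(set(scores))
    cands = [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])] or [uniq[0]]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = None
    for c in cands:
        tp = sum(1 for s, y in zip(scores, labels) if s >= c and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < c and y == 0)
        j = tp / n_pos + tn / n_neg - 1.0
        if best is None or j > best[1] + 1e-15:
            best = (c, j)
    return best


def km_bruteforce(times, events):
    """Product-limit S(t) at each distinct time, as {time: survival}."""
    pairs = sorted(zip(times, events))
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        n_at_risk = sum(1 for u, _ in pairs if u >= t)
        d = sum(1 for u, e in pairs if u == t and e == 1)
        if d:
            s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def logrank_bruteforce(ta, ea, tb, eb):
    """Explicit O/E/V table per distinct event time; returns the chi-square."""
    event_times = sorted(
        set([t for t, e in zip(ta, ea) if e == 1] + [t for t, e in zip(tb, eb) if e == 1])
    )
    o_minus_e = 0.0
    v = 0.0
    for t in event_times:
        na = sum(1 for u in ta if u >= t)
        nb = sum(1 for u in tb if u >= t)
        n = na + nb
        da = sum(1 for u, e in zip(ta, ea) if u == t and e == 1)
        db = sum(1 for u, e in zip(tb, eb) if u == t and e == 1)
        d = da + db
        if n < 2 or d == 0:
            continue
        o_minus_e += da - d * na / n
        v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / v) if v > 0 else 0.0


def fisher_two_sided_bruteforce(table):
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose probability
    does not exceed the observed one (with the conventional 1 + 1e-7
    relative guard for floating-point ties).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if float(pmf(k)) <= float(p_obs) * (1 + 1e-7):
            total += pmf(k)
    return float(total)


def hypergeom_upper_tail(k, M, K, n):
    """P(X >= k) for X ~ Hypergeom(M, K, n), exact fractions."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(M - K, n - j), comb(M, n))
    return float(total)


def pearson_p_bruteforce(r, n):
    """Two-sided p of a Pearson correlation from the t closed form (df n-2)."""
    from scipy.stats import t as tdist

    t = r * sqrt((n - 2) / (1 - r**2))
    return 2.0 * float(tdist.sf(abs(t), df=n - 2))


def tom_bruteforce(a):
    """Topological overlap by explicit triple loops."""
    a = np.asarray(a, dtype=float)
    m = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(m) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def kkt_residual(X, y, coef, alpha):
    """Max violation of the LASSO subgradient conditions on centered data.

    Objective: (1/2n) ||y - X b||^2 + alpha ||b||_1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    g = X.T @ (y - X @ coef) / n
    res = 0.0
    for j, b in enumerate(coef):
        if b != 0:
            res = max(res, abs(g[j] - alpha * np.sign(b)))
        else:
            res = max(res, max(abs(g[j]) - alpha, 0.0))
    return res
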