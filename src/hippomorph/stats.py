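"""Nonparametric cohort statistics: Mann-Whitney U, Spearman's rho, and
per-family Benjamini-Hochberg FDR correction.

Small samples get exact tests: the Mann-Whitney p-value enumerates every
group labeling (the tail of U = min(U_a, U_b), which is inherently
two-sided), and the Spearman p-value enumerates rank permutations. Larger
samples fall back to tie-corrected normal approximations. Midranks handle
ties throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps

EXACT_MWU_MAX_N = 16  # exact enumeration up to C(16, 8) = 12870 labelings
EXACT_SPEARMAN_MAX_N = 8  # 8! = 40320 permutations


@dataclass(frozen=True)
class StatResult:
    outcome: str
    covariate: str
    test: str  # "U" or "rho"
    statistic: float | None
    p_raw: float | None
    family: str
    p_adjusted: float | None
    n: int
    note: str = ""


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_a, U_b).

    ``mode='exact'`` enumerates all C(n_a+n_b, n_a) labelings of the pooled
    midranks and reports the tail probability P(U <= U_observed); because
    min-U is symmetric in the two groups this tail is already two-sided.
    ``mode='approx'`` uses the tie-corrected normal approximation with
    continuity correction. ``'auto'`` switches at n_a + n_b <= 16.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u_obs = min(u_a, u_b)

    if mode == "auto":
        mode = "exact" if na + nb <= EXACT_MWU_MAX_N else "approx"
    if mode == "exact":
        n = na + nb
        idx = range(n)
        count = 0
        total = math.comb(n, na)
        base = na * (na + 1) / 2.0
        for comb in combinations(idx, na):
            ua = ranks[list(comb)].sum() - base
            if min(ua, na * nb - ua) <= u_obs + 1e-9:
                count += 1
        return float(u_obs), count / total
    if mode == "approx":
        n = na + nb
        mu = na * nb / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
        sigma2 = na * nb / 12.0 * ((n + 1.0) - tie_term)
        if sigma2 <= 0:
            return float(u_obs), 1.0
        z = (u_obs + 0.5 - mu) / math.sqrt(sigma2)  # continuity toward the mean
        return float(u_obs), float(min(1.0, 2.0 * sps.norm.cdf(z)))
    raise ValueError(f"unknown mode: {mode!r}")


def spearman_rho(x, y, mode: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    Exact mode enumerates all permutations of the y-ranks and reports the
    fraction with |rho| at least as extreme. Raises ValueError for constant
    input (rho undefined) or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for constant input")
    rx = _midranks(x)
    ry = _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    n = x.size
    if mode == "auto":
        mode = "exact" if n <= EXACT_SPEARMAN_MAX_N else "approx"
    if mode == "exact":
        cx = rx - rx.mean()
        denom = math.sqrt((cx**2).sum())
        count = total = 0
        cys = np.array(list(permutations(ry)), dtype=float)
        cys -= ry.mean()
        denom_y = math.sqrt((cys[0] ** 2).sum())
        rhos = cys @ cx / (denom * denom_y)
        total = len(rhos)
        count = int((np.abs(rhos) >= abs(rho) - 1e-9).sum())
        return rho, count / total
    if mode == "approx":
        res = sps.spearmanr(x, y)
        return rho, float(res.pvalue)
    raise ValueError(f"unknown mode: {mode!r}")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment within one family of tests.

    adjusted_(i) = min_{j >= i} (m / j) * p_(j), capped at 1, mapped back to
    the input order. Apply separately per analysis family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def adjust_within_families(results: list[StatResult]) -> list[StatResult]:
    """Fill ``p_adjusted`` with BH applied separately within each family."""
    from dataclasses import replace

    by_family: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        if r.p_raw is not None:
            by_family.setdefault(r.family, []).append(i)
    out = list(results)
    for idxs in by_family.values():
        adj = benjamini_hochberg([results[i].p_raw for i in idxs])
        for i, a in zip(idxs, adj):
            out[i] = replace(results[i], p_adjusted=float(a))
    return out
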