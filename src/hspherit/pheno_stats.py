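"""Fixed-effects phenotypic comparisons.

One- and two-way ANOVA of immune-challenge responses (type-III sums of
squares on an effects-coded full-rank parameterisation, so unbalanced data
are handled consistently with LS-means logic), assumption checks
(Shapiro-Wilk normality, Levene/Brown-Forsythe variance homogeneity),
pairwise LS-mean comparisons with sequential-Bonferroni (Holm) correction,
and a compact-letter display of the significance pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "anova",
    "levene_test",
    "normality_check",
    "PairwiseComparisons",
    "lsmeans_pairwise",
    "sequential_bonferroni",
]


@dataclass(frozen=True)
class AnovaResult:
    terms: pd.DataFrame  # term, df, sum_sq, F, p
    residual_df: int
    residual_ms: float
    grand_mean: float
    dropped_terms: tuple[str, ...] = ()

    def p_value(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r}")
        return float(row["p"].iloc[0])


def _effect_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero coding: k-1 columns; last level coded -1 on each."""
    out = np.zeros((codes.size, k - 1))
    for j in range(k - 1):
        out[codes == j, j] = 1.0
    out[codes == k - 1, :] = -1.0
    return out


def anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str] | tuple[str, ...],
    interaction: bool = True,
) -> AnovaResult:
    """One- or two-way fixed-effects ANOVA with type-III sums of squares.

    Each term's SS is the Wald quadratic form of its effects-coded
    coefficients in the full model, which coincides with classical
    type III and, on balanced data, with sequential sums of squares.
    The interaction is dropped (and reported) when empty cells make it
    inestimable.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factor names required")
    df = data.dropna(subset=[response] + factors)
    y = df[response].to_numpy(dtype=float)
    n = y.size

    blocks: dict[str, np.ndarray] = {}
    level_counts: dict[str, int] = {}
    codes_map: dict[str, np.ndarray] = {}
    for f in factors:
        lv = sorted(df[f].astype(str).unique())
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        codes = df[f].astype(str).map({v: i for i, v in enumerate(lv)}).to_numpy()
        codes_map[f] = codes
        level_counts[f] = len(lv)
        blocks[f] = _effect_code(codes, len(lv))

    dropped: list[str] = []
    if len(factors) == 2 and interaction:
        f1, f2 = factors
        n_cells_possible = level_counts[f1] * level_counts[f2]
        observed_cells = len(set(zip(codes_map[f1], codes_map[f2])))
        if observed_cells < n_cells_possible:
            dropped.append(f"{f1}:{f2}")
        else:
            a, b = blocks[f1], blocks[f2]
            inter = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
            blocks[f"{f1}:{f2}"] = inter

    term_names = list(blocks.keys())
    X_parts = [np.ones((n, 1))] + [blocks[t] for t in term_names]
    X = np.hstack(X_parts)
    p = X.shape[1]
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    res_df = n - p
    mse = sse / res_df

    rows = []
    start = 1
    for t in term_names:
        w = blocks[t].shape[1]
        idx = np.arange(start, start + w)
        start += w
        bt = beta[idx]
        ss = float(bt @ np.linalg.solve(XtX_inv[np.ix_(idx, idx)], bt))
        F = (ss / w) / mse
        rows.append(
            {
                "term": t,
                "df": w,
                "sum_sq": ss,
                "F": F,
                "p": float(sps.f.sf(F, w, res_df)),
            }
        )
    return AnovaResult(
        terms=pd.DataFrame(rows),
        residual_df=res_df,
        residual_ms=mse,
        grand_mean=float(np.mean(y)),
        dropped_terms=tuple(dropped),
    )


def levene_test(
    data: pd.DataFrame,
    response: str,
    group: str,
    *,
    center: str = "median",
) -> tuple[float, tuple[int, int], float]:
    """Levene's homogeneity-of-variance test (median-centered by default).

    The median-centered variant (Brown-Forsythe) is robust to non-normality;
    ``center="mean"`` gives the classical form.  Returns (W, (df1, df2), p).
    """
    df = data.dropna(subset=[response, group])
    samples = [g[response].to_numpy(dtype=float) for _, g in df.groupby(group)]
    if len(samples) < 2:
        raise ValueError("at least two groups required")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    w, p = sps.levene(*samples, center=center)
    k, n = len(samples), sum(len(s) for s in samples)
    return float(w), (k - 1, n - k), float(p)


def normality_check(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk test of normality. Valid for 3 <= n <= 5000."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(r) == 0:
        raise ValueError("constant input: normality test undefined")
    stat, p = sps.shapiro(r)
    return float(stat), float(p)


def sequential_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down ('sequential Bonferroni') adjusted p-values.

    Adjusted p of the i-th smallest raw p is max over j<=i of (m-j+1)*p_(j),
    capped at 1; returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1 or not np.isfinite(p).all()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    # step-down scaling, made monotone non-decreasing in rank, capped at 1
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


@dataclass(frozen=True)
class PairwiseComparisons:
    table: pd.DataFrame  # group_i, group_j, diff, se, t, p_raw, p_adj, significant
    letters: dict[str, str]
    alpha: float


def _letter_display(
    groups: list[str], means: dict[str, float], sig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by greedy insertion on the non-significance graph.

    Groups sharing a letter are not significantly different.  Groups are
    processed in ascending mean order (ties by label).
    """
    ordered = sorted(groups, key=lambda g: (means[g], g))
    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all(
                (g, h) not in sig_pairs and (h, g) not in sig_pairs for h in s
            ):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets fully contained in another
    keep = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if j != i)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, keep):
        for g in s:
            out[g] += letter
    return out


def lsmeans_pairwise(
    data: pd.DataFrame,
    response: str,
    group: str,
    *,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> PairwiseComparisons:
    """All pairwise LS-mean contrasts for one grouping factor.

    LS-means from the cell-means model equal group means; contrast SEs use
    the pooled residual mean square.  P-values are Holm-adjusted by default
    (``adjust="none"`` disables correction).  The letter display marks groups
    not separable at ``alpha``.
    """
    df = data.dropna(subset=[response, group])
    gb = df.groupby(df[group].astype(str))[response]
    means = gb.mean().to_dict()
    counts = gb.count().to_dict()
    groups = sorted(means)
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if min(counts.values()) < 1 or len(df) <= len(groups):
        raise ValueError("insufficient replication for a residual mean square")
    n = len(df)
    k = len(groups)
    sse = float(
        sum(((g - g.mean()) ** 2).sum() for _, g in gb)
    )
    res_df = n - k
    mse = sse / res_df

    rows = []
    for gi, gj in combinations(groups, 2):
        diff = means[gi] - means[gj]
        se = np.sqrt(mse * (1.0 / counts[gi] + 1.0 / counts[gj]))
        t = diff / se
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "diff": diff,
                "se": se,
                "t": t,
                "p_raw": float(2.0 * sps.t.sf(abs(t), res_df)),
            }
        )
    tab = pd.DataFrame(rows)
    if adjust == "holm":
        tab["p_adj"] = sequential_bonferroni(tab["p_raw"].to_numpy())
    elif adjust == "none":
        tab["p_adj"] = tab["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    tab["significant"] = tab["p_adj"] <= alpha
    sig_pairs = {
        (r.group_i, r.group_j) for r in tab.itertuples() if r.significant
    }
    letters = _letter_display(groups, means, sig_pairs)
    return PairwiseComparisons(table=tab, letters=letters, alpha=alpha)
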