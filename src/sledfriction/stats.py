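"""Statistical battery for friction-feature tables.

Between-species differences are tested by one-way ANOVA with an
assumption gate (Shapiro-Wilk on residuals, Levene across groups) that
falls back to the Kruskal-Wallis rank test; significant omnibus results
are followed by Tukey HSD pairwise comparisons summarised as a compact
letter display.  Within-specimen direction effects (and anisotropy
ratios against 1) use the paired Wilcoxon signed-rank test, exact for
small samples.  Bivariate structure uses Spearman rank correlation,
ordinary least squares, and standardized major axis (SMA) regression --
the symmetric line fit used when both variables carry error, whose
slope is sign(r) * sd(y)/sd(x).
"""

from __future__ import annotations

from itertools import combinations
from string import ascii_lowercase

import numpy as np
from scipy import stats as sps

from .io import StatResult, ValidationError

__all__ = [
    "GroupedSample",
    "kruskal_wallis",
    "one_way_anova",
    "tukey_hsd_letters",
    "paired_wilcoxon",
    "rank_correlation",
    "ols_fit",
    "sma_fit",
]


class GroupedSample:
    """Numeric observations grouped by label, optionally paired."""

    def __init__(self, groups: dict[str, np.ndarray]):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        if len(self.groups) < 2:
            raise ValidationError("need >= 2 groups")
        for k, v in self.groups.items():
            if len(v) == 0:
                raise ValidationError(f"group {k!r} has no observations")

    @classmethod
    def from_frame(cls, df, group_col: str, value_col: str) -> "GroupedSample":
        return cls(
            {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}
        )

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def values(self) -> list[np.ndarray]:
        return list(self.groups.values())


# ---------------------------------------------------------------------------
# Omnibus tests
# ---------------------------------------------------------------------------


def kruskal_wallis(data: GroupedSample) -> StatResult:
    """Kruskal-Wallis rank test across groups (tie-corrected H,
    chi-square p on k-1 df).  All values identical -> H = 0, p = 1."""
    vals = data.values
    pooled = np.concatenate(vals)
    k = len(vals)
    if np.all(pooled == pooled[0]):
        return StatResult(
            method="kruskal_wallis", statistic=0.0, df=k - 1, p_value=1.0,
            notes="all values tied; H defined as 0",
        )
    h, p = sps.kruskal(*vals)
    return StatResult(method="kruskal_wallis", statistic=float(h), df=k - 1,
                      p_value=float(p))


def one_way_anova(data: GroupedSample, gate_alpha: float = 0.05) -> StatResult:
    """One-way ANOVA with an assumption gate.

    Shapiro-Wilk on the pooled residuals and Levene's test across groups
    are run first; if either rejects at ``gate_alpha`` the analysis
    switches to :func:`kruskal_wallis` and the switch is recorded in
    ``notes``.
    """
    vals = data.values
    k = len(vals)
    n = sum(len(v) for v in vals)
    if any(len(v) < 2 for v in vals):
        raise ValidationError("each group needs >= 2 observations for ANOVA")
    if all(np.all(v == v[0]) for v in vals) and len({v[0] for v in vals}) <= 1:
        raise ValidationError("degenerate data: zero variance everywhere")
    residuals = np.concatenate([v - np.mean(v) for v in vals])
    if np.allclose(residuals, 0):
        raise ValidationError("degenerate data: zero within-group variance")
    sw_p = float(sps.shapiro(residuals).pvalue)
    lev_p = float(sps.levene(*vals).pvalue)
    if sw_p < gate_alpha or lev_p < gate_alpha:
        result = kruskal_wallis(data)
        result.notes = (
            f"assumption gate failed (Shapiro p={sw_p:.3g}, Levene p={lev_p:.3g}); "
            "switched to Kruskal-Wallis. " + result.notes
        ).strip()
        result.extra.update(shapiro_p=sw_p, levene_p=lev_p, switched=True)
        return result
    f, p = sps.f_oneway(*vals)
    return StatResult(
        method="one_way_anova", statistic=float(f), df=(k - 1, n - k),
        p_value=float(p), extra={"shapiro_p": sw_p, "levene_p": lev_p, "switched": False},
    )


# ---------------------------------------------------------------------------
# Post hoc letters
# ---------------------------------------------------------------------------


def _maximal_cliques(adj: list[set[int]]) -> list[set[int]]:
    """Bron-Kerbosch maximal-clique enumeration (group counts are tiny)."""
    cliques: list[set[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(range(len(adj))), set())
    return cliques


def _letters_from_pmatrix(
    labels: list[str], means: np.ndarray, pmat: np.ndarray, alpha: float
) -> dict[str, str]:
    """Compact letter display: one letter per maximal clique of the
    non-significance graph (insert-and-absorb endpoint), so two groups
    share a letter iff their pairwise p >= alpha.  Letter order follows
    descending group means."""
    k = len(labels)
    adj = [
        {j for j in range(k) if j != i and pmat[i, j] >= alpha} for i in range(k)
    ]
    cliques = _maximal_cliques(adj)
    # letters ordered by the best (highest-mean) member of each clique
    cliques.sort(key=lambda c: (min(float(-means[g]) for g in c), sorted(c)))
    letters = {i: "" for i in range(k)}
    for li, col in enumerate(cliques):
        ch = ascii_lowercase[li % 26] * (1 + li // 26)
        for gi in sorted(col):
            letters[gi] += ch
    return {labels[i]: "".join(sorted(letters[i])) or "?" for i in range(k)}


def _rank_transform(data: GroupedSample) -> GroupedSample:
    pooled = np.concatenate(data.values)
    ranks = sps.rankdata(pooled)
    out = {}
    start = 0
    for label, v in data.groups.items():
        out[label] = ranks[start : start + len(v)]
        start += len(v)
    return GroupedSample(out)


def tukey_hsd_letters(
    data: GroupedSample, alpha: float = 0.05, on_ranks: bool = False
) -> StatResult:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal n) with a compact
    letter display.

    ``on_ranks=True`` runs the comparisons on pooled mid-ranks -- the
    post hoc companion to a Kruskal-Wallis omnibus.  Letters follow
    descending group means; groups sharing a letter do not differ at
    family level ``alpha``.
    """
    work = _rank_transform(data) if on_ranks else data
    labels = work.labels
    vals = work.values
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    res = sps.tukey_hsd(*vals)
    pmat = np.asarray(res.pvalue)
    means = np.array([np.mean(v) for v in data.values])  # display on raw scale
    letters = _letters_from_pmatrix(labels, means, pmat, alpha)
    return StatResult(
        method="tukey_hsd" + ("_on_ranks" if on_ranks else ""),
        statistic=float("nan"),
        p_value=float(np.min(pmat[np.triu_indices(len(labels), 1)])),
        group_letters=letters,
        extra={"pairwise_p": pmat, "labels": labels},
        notes="rank-transformed (post Kruskal-Wallis)" if on_ranks else "",
    )


# ---------------------------------------------------------------------------
# Paired and bivariate tests
# ---------------------------------------------------------------------------

EXACT_WILCOXON_MAX_N = 25


def paired_wilcoxon(
    x: np.ndarray, y: np.ndarray | float = 0.0
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    ``y`` may be a paired vector or a scalar null value (use
    ``paired_wilcoxon(ratios, 1.0)`` to test anisotropy against 1).
    Zero differences are dropped; with n <= 25 and no tied |d| the exact
    null distribution is enumerated, otherwise the normal approximation
    with continuity and tie correction is used.  All differences zero
    -> p = 1 with a note.
    """
    x = np.asarray(x, dtype=float)
    d = x - (np.asarray(y, dtype=float) if np.ndim(y) else float(y))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult(method="wilcoxon_signed_rank", statistic=0.0,
                          p_value=1.0, notes="all differences zero")
    if n < 3:
        raise ValidationError("need >= 3 nonzero differences")
    ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_WILCOXON_MAX_N and not ties:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        mode = "exact"
    else:
        res = sps.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
        mode = "normal approximation (continuity + tie corrected)"
    return StatResult(
        method="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(np.median(d)),
        extra={"n": n, "mode": mode},
        notes=mode,
    )


def rank_correlation(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Spearman rank correlation with tie-corrected p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors of >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult(method="spearman_rho", statistic=float(rho),
                      estimate=float(rho), p_value=float(p))


def ols_fit(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Ordinary least-squares line with R^2 and the slope t-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors of >= 3")
    if np.all(x == x[0]):
        raise ValidationError("constant predictor")
    res = sps.linregress(x, y)
    return StatResult(
        method="ols",
        statistic=float(res.slope),
        estimate=float(res.slope),
        p_value=float(res.pvalue),
        extra={
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "stderr": float(res.stderr),
        },
    )


def sma_fit(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Standardized major axis regression.

    The SMA slope is ``sign(r) * sd(y)/sd(x)`` and the intercept passes
    through the centroid.  The slope confidence interval uses the
    classical relation to the F distribution:
    ``b * (sqrt(B + 1) +/- sqrt(B))`` with
    ``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)``.  ``extra`` reports
    whether the CI excludes a slope of 1 (isometry).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("need equal-length vectors of >= 3")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValidationError("constant variable: SMA undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise ValidationError("zero correlation: SMA slope sign and CI undefined")
    b = float(np.sign(r) * sy / sx)
    intercept = float(np.mean(y) - b * np.mean(x))
    fcrit = float(sps.f.ppf(1 - alpha, 1, n - 2))
    big_b = fcrit * (1 - r**2) / (n - 2)
    lo = b * (np.sqrt(big_b + 1) - np.sqrt(big_b))
    hi = b * (np.sqrt(big_b + 1) + np.sqrt(big_b))
    if b < 0:
        lo, hi = hi, lo
    r2 = r**2
    return StatResult(
        method="sma",
        statistic=b,
        estimate=b,
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=float("nan"),
        extra={
            "intercept": intercept,
            "r_squared": r2,
            "excludes_one": bool(lo > 1.0 or hi < 1.0),
            "n": n,
        },
    )
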