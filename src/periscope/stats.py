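"""Nonparametric group comparisons and summary conventions.

Defaults follow the field's usual pairing: two groups → two-tailed
Mann-Whitney U (exact null for small tie-free samples, normal approximation
with tie correction otherwise); three or more groups → Kruskal-Wallis H with
Dunn's pairwise post-hoc and Bonferroni adjustment. Parametric counterparts
(Welch's t, one-way ANOVA) are available behind the same interface since
figure legends in this literature often name the parametric test while the
methods name the nonparametric one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class Contrast:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class GroupComparison:
    test_name: str
    method: str                    # e.g. "exact", "asymptotic-tie-corrected"
    groups: dict[str, np.ndarray]
    statistic: float
    p_value: float
    contrasts: list[Contrast] = field(default_factory=list)

    @property
    def n_per_group(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def summary(self) -> str:
        lines = [f"{self.test_name} ({self.method}): statistic={self.statistic:.4g}, "
                 f"p={self.p_value:.4g} {significance_stars(self.p_value)}"]
        for k, v in self.groups.items():
            lines.append(f"  {k}: n={len(v)}, median={np.median(v):.4g}")
        for c in self.contrasts:
            lines.append(f"  {c.group_a} vs {c.group_b}: z={c.statistic:.3f}, "
                         f"p={c.p_value:.4g}, p_adj={c.p_adjusted:.4g} "
                         f"{significance_stars(c.p_adjusted)}")
        return "\n".join(lines)


def significance_stars(p: float) -> str:
    """The usual star convention; raw p is always reported alongside."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_arrays(*samples) -> list[np.ndarray]:
    out = []
    for s in samples:
        a = np.asarray(s, dtype=float).ravel()
        if len(a) < 2:
            raise ValueError("each sample needs at least 2 observations")
        if not np.all(np.isfinite(a)):
            raise ValueError("samples must be finite")
        out.append(a)
    return out


_EXACT_MAX_N = 10


def mann_whitney(a, b, labels: tuple[str, str] = ("a", "b"),
                 parametric: bool = False) -> GroupComparison:
    """Two-tailed two-sample comparison (Mann-Whitney U by default).

    The exact permutation null is used when the smaller sample has at most
    10 observations and the pooled data is tie-free; past that size the
    normal approximation with tie and continuity corrections has converged
    to the exact null (within 0.01 on the p-value), and is used instead.
    With ``parametric=True`` runs Welch's unequal-variance t-test.
    """
    a, b = _as_arrays(a, b)
    if parametric:
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison("Welch t-test", "welch", {labels[0]: a, labels[1]: b},
                               float(res.statistic), float(res.pvalue))
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(a), len(b)) <= _EXACT_MAX_N) and not ties
    method = "exact" if exact else "asymptotic-tie-corrected"
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return GroupComparison("Mann-Whitney U", method, {labels[0]: a, labels[1]: b},
                           float(res.statistic), float(res.pvalue))


def _dunn_contrasts(groups: dict[str, np.ndarray], reference: str | None) -> list[Contrast]:
    """Dunn's z-statistics on pooled mid-ranks with tie correction;
    Bonferroni adjustment over the reported contrasts."""
    names = list(groups)
    values = np.concatenate([groups[k] for k in names])
    sizes = [len(groups[k]) for k in names]
    ranks = sps.rankdata(values)
    n_total = len(values)

    mean_ranks = {}
    start = 0
    for k, sz in zip(names, sizes):
        mean_ranks[k] = ranks[start:start + sz].mean()
        start += sz

    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    if reference is not None and reference in names:
        ri = names.index(reference)
        pairs.sort(key=lambda ij: 0 if ri in ij else 1)

    m = len(pairs)
    contrasts = []
    for i, j in pairs:
        a, b = names[i], names[j]
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                     * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        contrasts.append(Contrast(a, b, float(z), float(p), float(min(1.0, p * m))))
    return contrasts


def kruskal_dunn(groups: dict[str, list | np.ndarray], reference: str | None = None,
                 parametric: bool = False) -> GroupComparison:
    """Kruskal-Wallis H across ≥ 3 groups with Dunn's post-hoc contrasts.

    Contrasts against ``reference`` (e.g. the wild-type condition) are
    reported first; pairwise p-values are Bonferroni-adjusted over all
    reported contrasts. With ``parametric=True`` runs one-way ANOVA with
    pairwise Welch t contrasts instead.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use mann_whitney for two)")
    arrays = {k: v for k, v in zip(groups, _as_arrays(*groups.values()))}

    if parametric:
        res = sps.f_oneway(*arrays.values())
        comp = GroupComparison("one-way ANOVA", "f-test", arrays,
                               float(res.statistic), float(res.pvalue))
        names = list(arrays)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        m = len(pairs)
        for a, b in pairs:
            t = sps.ttest_ind(arrays[a], arrays[b], equal_var=False)
            comp.contrasts.append(Contrast(a, b, float(t.statistic), float(t.pvalue),
                                           float(min(1.0, t.pvalue * m))))
        return comp

    values = np.concatenate(list(arrays.values()))
    if np.all(values == values[0]):
        return GroupComparison("Kruskal-Wallis", "degenerate", arrays, 0.0, 1.0)
    res = sps.kruskal(*arrays.values())
    comp = GroupComparison("Kruskal-Wallis", "chi2-approx-tie-corrected", arrays,
                           float(res.statistic), float(res.pvalue))
    comp.contrasts = _dunn_contrasts(arrays, reference)
    return comp


def summary_percentiles(sample) -> dict[str, float]:
    """5/25/50/75/95 percentiles (linear interpolation between order
    statistics), mean and sample SD (n−1 denominator)."""
    a = np.asarray(sample, dtype=float).ravel()
    if len(a) < 1:
        raise ValueError("sample must be non-empty")
    out = {f"p{p}": float(np.percentile(a, p, method="linear")) for p in (5, 25, 50, 75, 95)}
    out["mean"] = float(a.mean())
    out["sd"] = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return out
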