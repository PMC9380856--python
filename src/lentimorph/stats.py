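"""Statistical battery for the morphometric indices.

Three analyses, mirroring common radiology practice:

* **Group comparison** — per index, a Shapiro-Wilk normality gate decides
  the path jointly over all groups: if every group is compatible with
  normality (p >= alpha in each), one-way ANOVA with Fisher's LSD pairwise
  comparisons (plain pairwise t-tests on the pooled within-group variance,
  no multiplicity correction — that is what LSD means); otherwise pairwise
  two-sided Mann-Whitney U tests.
* **Inter-rater agreement** — ICC(2,1): two-way random effects, absolute
  agreement, single measurement, computed from the mean squares of the
  subjects x raters table. Bands: ICC < 0.3 slight, 0.3-0.7 moderate
  (inclusive), > 0.7 good.
* **ROC** — empirical ROC between a positive and a comparison group, AUC by
  the rank (Mann-Whitney) statistic, cutoff at the candidate threshold
  maximizing Youden's J = sensitivity + specificity - 1.  Candidates are
  midpoints between adjacent sorted unique values; orientation is chosen so
  the positive group lies on the positive side (AUC >= 0.5) and is
  reported, ties in J break toward higher sensitivity.

:func:`run_full_analysis` orchestrates all three over an indices table and
selects for ROC exactly the indices whose positive-vs-comparison p-value is
below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import INDEX_COLUMNS, PER_RATER_INDEX_COLUMNS

__all__ = [
    "GroupComparison",
    "RocResult",
    "IccResult",
    "AnalysisReport",
    "normality_gate",
    "compare_groups",
    "icc_two_rater",
    "icc_agreement_level",
    "roc_analysis",
    "run_full_analysis",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    index_name: str
    test_used: str  # "ANOVA_LSD" | "MannWhitneyU"
    pairwise_p: dict  # (group_a, group_b) -> p
    normality_p: dict  # group -> Shapiro-Wilk p (nan for degenerate groups)
    anova_p: float | None = None  # omnibus p on the parametric path

    def p(self, a: str, b: str) -> float:
        if (a, b) in self.pairwise_p:
            return self.pairwise_p[(a, b)]
        return self.pairwise_p[(b, a)]


@dataclass(frozen=True)
class RocResult:
    index_name: str
    positive_group: str
    comparison_group: str
    orientation: str  # "lower_is_positive" | "higher_is_positive"
    auc: float
    cutoff: float  # original index units
    youden_j: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame = field(compare=False, repr=False, default=None)


@dataclass(frozen=True)
class IccResult:
    index_name: str
    icc: float
    agreement_band: str  # "slight" | "moderate" | "good"
    model: str = "two-way random, absolute agreement, single rater (ICC2,1)"
    group: str | None = None


def normality_gate(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> tuple[str, dict[str, float]]:
    """Decide ``"parametric"`` vs ``"nonparametric"`` jointly over groups.

    Parametric iff the Shapiro-Wilk p-value is >= ``alpha`` in *every*
    group.  A constant-valued group cannot be tested for normality and
    routes to the nonparametric path with a warning.
    """
    pvals: dict[str, float] = {}
    route = "parametric"
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise ValueError(f"group {name!r} has n={vals.size} < 3")
        if np.ptp(vals) == 0:
            warnings.warn(
                f"group {name!r} is constant-valued; using the nonparametric path",
                stacklevel=2,
            )
            pvals[name] = float("nan")
            route = "nonparametric"
            continue
        p = float(sps.shapiro(vals).pvalue)
        pvals[name] = p
        if p < alpha:
            route = "nonparametric"
    return route, pvals


def _lsd_pairwise(groups: dict[str, np.ndarray]) -> tuple[dict, float]:
    """Fisher's LSD: pairwise t on the pooled within-group variance,
    df = N - k, no multiplicity correction. Returns pairwise p and the
    omnibus ANOVA p."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    n_tot = sum(a.size for a in arrays.values())
    k = len(arrays)
    df_err = n_tot - k
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_err
    anova_p = float(sps.f_oneway(*arrays.values()).pvalue)
    pair_p = {}
    for a, b in combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        se = np.sqrt(mse * (1.0 / xa.size + 1.0 / xb.size))
        t = (xa.mean() - xb.mean()) / se
        pair_p[(a, b)] = float(2.0 * sps.t.sf(abs(t), df_err))
    return pair_p, anova_p


def _mwu_pairwise(groups: dict[str, np.ndarray]) -> dict:
    pair_p = {}
    for a, b in combinations(groups, 2):
        res = sps.mannwhitneyu(
            groups[a], groups[b], alternative="two-sided", method="auto"
        )
        pair_p[(a, b)] = float(res.pvalue)
    return pair_p


def compare_groups(
    table: pd.DataFrame,
    index_name: str,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Normality-gated comparison of one index across all groups."""
    if index_name not in table.columns:
        raise KeyError(f"index {index_name!r} not in table")
    groups = {
        str(g): sub[index_name].to_numpy(dtype=float)
        for g, sub in table.groupby(group_col, sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    route, normality_p = normality_gate(groups, alpha=alpha)
    if route == "parametric":
        pair_p, anova_p = _lsd_pairwise(groups)
        return GroupComparison(index_name, "ANOVA_LSD", pair_p, normality_p, anova_p)
    return GroupComparison(index_name, "MannWhitneyU", _mwu_pairwise(groups), normality_p)


def icc_two_rater(values: np.ndarray, index_name: str = "") -> IccResult:
    """ICC(2,1) for an ``n x 2`` subjects-by-raters table.

    Two-way random effects, absolute agreement, single measurement::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, rater and residual mean squares.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected an n x 2 table, got shape {x.shape}")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    if np.isnan(x).any():
        raise ValueError("missing cells in the rater table")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return IccResult(index_name=index_name, icc=float(icc),
                     agreement_band=icc_agreement_level(float(icc)))


def icc_agreement_level(icc: float) -> str:
    """Agreement band: < 0.3 slight; 0.3-0.7 (inclusive) moderate; > 0.7 good."""
    if not -1 < icc <= 1:
        raise ValueError(f"ICC {icc} outside (-1, 1]")
    if icc < 0.3:
        return "slight"
    if icc <= 0.7:
        return "moderate"
    return "good"


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (midranks for ties)."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(
    table: pd.DataFrame,
    index_name: str,
    positive_group: str,
    comparison_group: str,
    group_col: str = "group",
) -> RocResult:
    """Empirical ROC of one index for positive vs comparison group."""
    pos = table.loc[table[group_col] == positive_group, index_name].to_numpy(float)
    neg = table.loc[table[group_col] == comparison_group, index_name].to_numpy(float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs n >= 2 for ROC")
    combined = np.concatenate([pos, neg])
    if np.ptp(combined) == 0:
        raise ValueError(f"index {index_name!r} is single-valued; ROC undefined")

    lower_is_positive = pos.mean() < neg.mean()
    sign = -1.0 if lower_is_positive else 1.0
    spos, sneg = sign * pos, sign * neg
    auc = _auc_rank(spos, sneg)

    # candidate cutoffs: midpoints between adjacent unique scores, plus
    # sentinels outside the data range so the (1,0)/(0,1) corners compete
    uniq = np.unique(np.concatenate([spos, sneg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    # classify positive when score >= cutoff; counts via sorted search so the
    # scan stays O(n log n) even for very large simulated groups
    spos_sorted, sneg_sorted = np.sort(spos), np.sort(sneg)
    sens = 1.0 - np.searchsorted(spos_sorted, cands, side="left") / spos.size
    spec = np.searchsorted(sneg_sorted, cands, side="left") / sneg.size
    j = sens + spec - 1.0
    best_j = j.max()
    # ties in J break toward higher sensitivity
    tied = np.flatnonzero(np.isclose(j, best_j))
    best = tied[np.argmax(sens[tied])]
    curve = pd.DataFrame(
        {"cutoff": sign * cands, "sensitivity": sens, "specificity": spec, "youden_j": j}
    )
    return RocResult(
        index_name=index_name,
        positive_group=positive_group,
        comparison_group=comparison_group,
        orientation="lower_is_positive" if lower_is_positive else "higher_is_positive",
        auc=auc,
        cutoff=float(sign * cands[best]),
        youden_j=float(j[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        curve=curve,
    )


@dataclass
class AnalysisReport:
    """All statistical outputs of one cohort analysis."""

    comparisons: list[GroupComparison]
    roc: list[RocResult]
    icc: list[IccResult]
    roc_pairs: list[tuple[str, str]]
    alpha: float = ALPHA

    def roc_indices(self, positive: str, comparison: str) -> list[str]:
        return [
            r.index_name
            for r in self.roc
            if r.positive_group == positive and r.comparison_group == comparison
        ]


def run_full_analysis(
    indices: pd.DataFrame,
    per_rater: pd.DataFrame | None = None,
    positive_group: str = "MSA-P",
    comparison_groups: tuple[str, ...] = ("PD", "CG"),
    index_names: list[str] | None = None,
    alpha: float = ALPHA,
) -> AnalysisReport:
    """Full battery: comparisons for every index, ROC for each index
    significant (p < alpha) between the positive group and each comparison
    group, and per-group two-rater ICC when a per-rater table is given."""
    index_names = index_names or [c for c in INDEX_COLUMNS if c in indices.columns]
    present = set(indices["group"].unique())
    comparison_groups = tuple(g for g in comparison_groups if g in present)
    if positive_group not in present or not comparison_groups:
        raise ValueError(
            f"groups {sorted(present)} lack the positive/comparison structure"
        )

    comparisons = [compare_groups(indices, name, alpha=alpha) for name in index_names]

    roc_results = []
    for comp_group in comparison_groups:
        for c in comparisons:
            if c.p(positive_group, comp_group) < alpha:
                roc_results.append(
                    roc_analysis(indices, c.index_name, positive_group, comp_group)
                )

    icc_results = []
    if per_rater is not None:
        for group, sub in per_rater.groupby("group", sort=False):
            wide_ok = sub.groupby("subject_id")["rater"].count()
            if (wide_ok != 2).any():
                raise ValueError(f"group {group}: not exactly 2 raters per subject")
            for name in PER_RATER_INDEX_COLUMNS:
                wide = sub.pivot(index="subject_id", columns="rater", values=name)
                res = icc_two_rater(wide.to_numpy(), index_name=name)
                icc_results.append(
                    IccResult(name, res.icc, res.agreement_band, res.model, str(group))
                )

    return AnalysisReport(
        comparisons=comparisons,
        roc=roc_results,
        icc=icc_results,
        roc_pairs=[(positive_group, g) for g in comparison_groups],
        alpha=alpha,
    )
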