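"""Intra- and inter-tumoral PD-L1 heterogeneity.

Intra-tumoral heterogeneity is assessed from two spatially separated cores
per lesion: the first core (sample_index 1) is the reference, the second
the comparison, and a lesion is *reclassified* when their tri-categorical
labels (negative / low / high) differ. Inter-tumoral heterogeneity compares
lesion-level mean scores between lesion types within a patient (primary vs
lymph-node metastasis, local recurrence, distant metastasis), again as a
3x3 category transition table, with a paired Wilcoxon signed-rank test on
the absolute values.

The module also houses the nonparametric test battery (Mann-Whitney U /
Kruskal-Wallis with Dunn-corrected post-hoc comparisons; Wilcoxon /
Friedman for paired designs) and the correlation dispatch (Spearman rho for
ratio data, Kendall tau-b for ordinal data, Phi for dichotomous data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CATEGORIES, categorize

__all__ = [
    "PairedComparison",
    "ReclassificationTable",
    "TestResult",
    "CorrelationResult",
    "HeterogeneityError",
    "intra_tumoral_reclassification",
    "inter_tumoral_discordance",
    "compare_groups",
    "dunn_posthoc",
    "correlate",
    "fisher_z_ci",
]

logger = logging.getLogger(__name__)

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


class HeterogeneityError(ValueError):
    """Invalid input to a heterogeneity analysis."""


@dataclass(frozen=True)
class PairedComparison:
    """One reference/comparison score pair and its categorical verdict."""

    unit_id: str
    reference_value: float
    comparison_value: float
    reference_category: str
    comparison_category: str

    @property
    def discordant(self) -> bool:
        return self.reference_category != self.comparison_category


@dataclass
class ReclassificationTable:
    """3x3 category transition counts, reference category in rows."""

    scheme: str
    counts: np.ndarray  # (3, 3) int, rows = reference, cols = comparison
    n_pairs: int

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def reclassification_rate(self) -> float:
        """Fraction of pairs whose category changed; NaN with zero pairs."""
        if self.n_pairs == 0:
            return float("nan")
        return (self.n_pairs - self.trace) / self.n_pairs

    @classmethod
    def from_pairs(cls, pairs: Sequence[PairedComparison], scheme: str) -> "ReclassificationTable":
        counts = np.zeros((3, 3), dtype=int)
        for p in pairs:
            counts[_CAT_INDEX[p.reference_category], _CAT_INDEX[p.comparison_category]] += 1
        return cls(scheme=scheme.upper(), counts=counts, n_pairs=len(pairs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(CATEGORIES, name="reference"),
            columns=pd.Index(CATEGORIES, name="comparison"),
        )

    def source_breakdown(self) -> pd.DataFrame:
        """Per reference category: how many pairs moved where.

        Mirrors statements like "52.6% of reference-negative lesions were
        reclassified to a low score". Fractions are relative to the row
        (reference-category) total.
        """
        rows = []
        for i, ref in enumerate(CATEGORIES):
            total = int(self.counts[i].sum())
            for j, comp in enumerate(CATEGORIES):
                if i == j:
                    continue
                rows.append(
                    {
                        "reference": ref,
                        "comparison": comp,
                        "n": int(self.counts[i, j]),
                        "n_reference": total,
                        "fraction": self.counts[i, j] / total if total else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def sankey(self) -> dict:
        """Sankey-ready JSON dict: category nodes and transition links."""
        nodes = [{"name": f"reference:{c}"} for c in CATEGORIES] + [
            {"name": f"comparison:{c}"} for c in CATEGORIES
        ]
        links = [
            {"source": i, "target": 3 + j, "value": int(self.counts[i, j])}
            for i in range(3)
            for j in range(3)
            if self.counts[i, j] > 0
        ]
        return {"scheme": self.scheme, "nodes": nodes, "links": links}


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    paired: bool
    adjusted: bool = False
    groups: tuple = ()


@dataclass(frozen=True)
class CorrelationResult:
    kind: str
    coefficient: float
    p_value: float
    n: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    note: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.coefficient)


# ---------------------------------------------------------------------------
# Reclassification


def _score_col(scheme: str) -> str:
    s = scheme.upper()
    if s not in ("CPS", "TPS"):
        raise HeterogeneityError(f"unknown scheme {scheme!r}")
    return s.lower()


def intra_tumoral_reclassification(
    scored_cores: pd.DataFrame, scheme: str = "CPS"
) -> tuple[ReclassificationTable, list[PairedComparison]]:
    """Reclassification between the two cores of each lesion.

    For every lesion with at least two QC-passing cores, the core with the
    lowest ``sample_index`` (ties broken by ``core_id``) is the reference
    and the next one the comparison; extra cores beyond the first two are
    ignored here (the assay design is two punches per specimen). Lesions
    with fewer than two QC-passing cores are skipped with a logged warning.
    """
    col = _score_col(scheme)
    pairs: list[PairedComparison] = []
    skipped = 0
    for lesion_id, grp in scored_cores.groupby("lesion_id", sort=True):
        passing = grp[grp["qc_pass"]].sort_values(["sample_index", "core_id"])
        if len(passing) < 2:
            skipped += 1
            continue
        ref, comp = passing.iloc[0], passing.iloc[1]
        pairs.append(
            PairedComparison(
                unit_id=str(lesion_id),
                reference_value=float(ref[col]),
                comparison_value=float(comp[col]),
                reference_category=categorize(float(ref[col]), scheme),
                comparison_category=categorize(float(comp[col]), scheme),
            )
        )
    if skipped:
        logger.warning(
            "intra-tumoral reclassification: skipped %d lesion(s) with <2 QC-passing cores",
            skipped,
        )
    return ReclassificationTable.from_pairs(pairs, scheme), pairs


def inter_tumoral_discordance(
    lesions: pd.DataFrame,
    type_a: str,
    type_b: str,
    scheme: str = "CPS",
) -> tuple[ReclassificationTable, list[PairedComparison], TestResult]:
    """Category discordance between two lesion types across patients.

    Only patients possessing QC-valid lesions of both types enter;
    ``type_a`` is the reference (the primary tumor, when present). When a
    patient has several lesions of one type their lesion-level means are
    averaged before pairing. The absolute paired values are compared with
    a two-tailed Wilcoxon signed-rank test.
    """
    col = _score_col(scheme)
    usable = lesions[~lesions["excluded"]]
    by_type = {
        t: usable[usable["lesion_type"] == t].groupby("patient_id")[col].mean()
        for t in (type_a, type_b)
    }
    common = by_type[type_a].index.intersection(by_type[type_b].index)
    if len(common) < 1:
        raise HeterogeneityError(
            f"no patient has both lesion types {type_a!r} and {type_b!r}"
        )
    multi = usable[usable["lesion_type"].isin([type_a, type_b])]
    n_multi = multi.groupby(["patient_id", "lesion_type"]).size()
    if (n_multi > 1).any():
        logger.info(
            "inter-tumoral discordance: averaged multiple lesions within type for %d patient-type group(s)",
            int((n_multi > 1).sum()),
        )
    pairs = [
        PairedComparison(
            unit_id=str(pid),
            reference_value=float(by_type[type_a][pid]),
            comparison_value=float(by_type[type_b][pid]),
            reference_category=categorize(float(by_type[type_a][pid]), scheme),
            comparison_category=categorize(float(by_type[type_b][pid]), scheme),
        )
        for pid in common
    ]
    table = ReclassificationTable.from_pairs(pairs, scheme)
    ref = np.array([p.reference_value for p in pairs])
    comp = np.array([p.comparison_value for p in pairs])
    test = _wilcoxon(ref, comp, name=f"wilcoxon[{type_a} vs {type_b}]")
    return table, pairs, test


# ---------------------------------------------------------------------------
# Test battery


def _wilcoxon(a: np.ndarray, b: np.ndarray, name: str = "wilcoxon") -> TestResult:
    # zero differences dropped (standard convention); all-zero -> p = 1
    diffs = np.asarray(a, float) - np.asarray(b, float)
    nonzero = int(np.count_nonzero(diffs))
    if nonzero == 0:
        return TestResult(name, statistic=0.0, p_value=1.0, n=0, paired=True)
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return TestResult(name, statistic=float(stat), p_value=float(p), n=nonzero, paired=True)


def compare_groups(
    groups: Mapping[str, Sequence[float]], paired: bool = False
) -> list[TestResult]:
    """Nonparametric group comparison, dispatching on design.

    Two unpaired groups -> Mann-Whitney U; more -> Kruskal-Wallis followed
    by Dunn-corrected pairwise comparisons. Two paired groups -> Wilcoxon
    signed-rank; more -> Friedman. All tests two-tailed. Identical data in
    all groups yields p = 1 rather than an error.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise HeterogeneityError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        empty = [k for k, a in zip(names, arrays) if len(a) == 0]
        raise HeterogeneityError(f"empty group(s): {empty}")
    if paired and len({len(a) for a in arrays}) != 1:
        raise HeterogeneityError("paired comparison requires equal-length groups")

    all_vals = np.concatenate(arrays)
    constant = np.all(all_vals == all_vals[0])
    n_total = int(sum(len(a) for a in arrays))

    if paired:
        if len(arrays) == 2:
            return [_wilcoxon(arrays[0], arrays[1])]
        if constant:
            return [TestResult("friedman", 0.0, 1.0, n_total, True)]
        stat, p = stats.friedmanchisquare(*arrays)
        return [TestResult("friedman", float(stat), float(p), n_total, True)]

    if len(arrays) == 2:
        if constant:
            return [TestResult("mann-whitney-u", float(len(arrays[0]) * len(arrays[1]) / 2), 1.0, n_total, False)]
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return [TestResult("mann-whitney-u", float(stat), float(p), n_total, False)]

    if constant:
        return [TestResult("kruskal-wallis", 0.0, 1.0, n_total, False)]
    stat, p = stats.kruskal(*arrays)
    results = [TestResult("kruskal-wallis", float(stat), float(p), n_total, False)]
    posthoc = dunn_posthoc(groups)
    for row in posthoc.itertuples():
        results.append(
            TestResult(
                test_name="dunn",
                statistic=float(row.z),
                p_value=float(row.p_adjusted),
                n=n_total,
                paired=False,
                adjusted=True,
                groups=(row.group_a, row.group_b),
            )
        )
    return results


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc rank comparisons after Kruskal-Wallis.

    Pairwise z statistics built from mean ranks of the pooled sample with
    the tie correction, two-sided p-values adjusted within the family by
    Bonferroni (capped at 1), so adjusted p >= unadjusted p always.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + len(a)].mean()))
        sizes.append(len(a))
        start += len(a)
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for i, j in combinations(range(len(names)), 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "z": z,
                "p_unadjusted": p,
                "p_adjusted": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations


def fisher_z_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Confidence interval for a correlation via Fisher's r-to-z transform."""
    if n < 4 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se))


def correlate(x: Sequence[float], y: Sequence[float], kind: str = "spearman") -> CorrelationResult:
    """Correlation dispatch: spearman | kendall_tau_b | phi.

    Zero variance in either vector yields an undefined-coefficient result
    (NaN with a note) rather than an exception. A Fisher-z confidence
    interval is attached when computable.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise HeterogeneityError("x and y must be equal-length 1-d vectors")
    n = len(xa)
    if n < 2:
        raise HeterogeneityError("need at least two paired observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(kind, float("nan"), float("nan"), n, note="zero variance")

    if kind == "spearman":
        rho, p = stats.spearmanr(xa, ya)
        coef = float(rho)
    elif kind == "kendall_tau_b":
        tau, p = stats.kendalltau(xa, ya, variant="b")
        coef = float(tau)
    elif kind == "phi":
        ux, uy = np.unique(xa), np.unique(ya)
        if len(ux) != 2 or len(uy) != 2:
            raise HeterogeneityError("phi requires two dichotomous vectors")
        table = pd.crosstab(xa, ya).to_numpy()
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        coef = math.sqrt(chi2 / n)
        # sign from the 2x2 determinant
        if table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0] < 0:
            coef = -coef
        p = float(p)
    else:
        raise HeterogeneityError(f"unknown correlation kind {kind!r}")

    ci_low, ci_high = fisher_z_ci(coef, n)
    return CorrelationResult(kind, coef, float(p), n, ci_low, ci_high)
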