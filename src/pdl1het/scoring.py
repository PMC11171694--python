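"""PD-L1 scoring of tissue-microarray cores.

Converts per-core cell-detection tallies into the two assay scores used to
select head-and-neck cancer patients for anti-PD-1 therapy:

* TPS (tumor proportion score) — percentage of viable tumor cells with
  membranous PD-L1 positivity.
* CPS (combined positive score) — 100 x (PD-L1-positive tumor cells +
  PD-L1-positive lymphocytes and macrophages) / viable tumor cells,
  capped at 100 by definition.

Cores with fewer than 100 viable tumor cells fail quality control; their
scores are still computed (for audit) but flagged and excluded from
lesion-level aggregation and all downstream statistics.

Scores are kept at full precision internally; rounding to one decimal is a
reporting concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoreCounts",
    "PDL1Score",
    "LesionScore",
    "ScoringError",
    "UndefinedScoreError",
    "CATEGORIES",
    "CATEGORY_BOUNDS",
    "QC_MIN_TUMOR_CELLS",
    "compute_scores",
    "categorize",
    "aggregate_lesion",
    "score_cores",
    "aggregate_lesions",
]

#: Minimum viable tumor cells per core required by the pharmDx protocol.
QC_MIN_TUMOR_CELLS = 100

#: Tri-categorical labels in increasing order of expression.
CATEGORIES = ("negative", "low", "high")

#: (low threshold, high threshold) per scheme; thresholds belong to the
#: upper category (CPS >= 1 is "low", CPS >= 20 is "high", etc.).
CATEGORY_BOUNDS = {"CPS": (1.0, 20.0), "TPS": (1.0, 50.0)}

LESION_TYPES = ("primary", "local_recurrence", "lymph_node_met", "distant_met")


class ScoringError(ValueError):
    """Invalid cell counts or score values."""


class UndefinedScoreError(ScoringError):
    """Score is mathematically undefined (no viable tumor cells)."""


@dataclass(frozen=True)
class CoreCounts:
    """Raw cell-detection tallies for one TMA core.

    ``sample_index`` orders the cores within their lesion; index 1 is the
    reference core for intra-tumoral comparisons.
    """

    core_id: str
    lesion_id: str
    patient_id: str
    n_tumor_viable: int
    n_tumor_pos: int
    n_immune_pos: int
    sample_index: int = 1

    def __post_init__(self) -> None:
        for name in ("n_tumor_viable", "n_tumor_pos", "n_immune_pos"):
            if getattr(self, name) < 0:
                raise ScoringError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.sample_index < 1:
            raise ScoringError(f"sample_index must be >= 1, got {self.sample_index}")
        if self.n_tumor_pos > self.n_tumor_viable:
            raise ScoringError(
                f"core {self.core_id!r}: n_tumor_pos ({self.n_tumor_pos}) exceeds "
                f"n_tumor_viable ({self.n_tumor_viable})"
            )


@dataclass(frozen=True)
class PDL1Score:
    """CPS/TPS values with QC status for one core (or one aggregated lesion)."""

    cps: float
    tps: float
    cps_raw: float
    qc_pass: bool
    n_tumor_viable: int


@dataclass
class LesionScore:
    """Lesion-level aggregate: arithmetic mean of the QC-passing core scores."""

    lesion_id: str
    lesion_type: str
    treated: bool
    score: PDL1Score | None
    per_core: list[PDL1Score] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        """True when no core passed QC; such lesions leave every analysis."""
        return self.score is None


def compute_scores(core: CoreCounts) -> PDL1Score:
    """Score one core.

    TPS = 100 * positive tumor cells / viable tumor cells.
    CPS = 100 * (positive tumor + positive immune cells) / viable tumor
    cells, capped at 100. QC fails below 100 viable tumor cells but the
    scores are still returned.

    Raises
    ------
    UndefinedScoreError
        If ``n_tumor_viable`` is zero (no denominator; distinct from a
        mere QC failure).
    """
    if core.n_tumor_viable == 0:
        raise UndefinedScoreError(
            f"core {core.core_id!r}: score undefined with zero viable tumor cells"
        )
    tps = 100.0 * core.n_tumor_pos / core.n_tumor_viable
    cps_raw = 100.0 * (core.n_tumor_pos + core.n_immune_pos) / core.n_tumor_viable
    return PDL1Score(
        cps=min(cps_raw, 100.0),
        tps=tps,
        cps_raw=cps_raw,
        qc_pass=core.n_tumor_viable >= QC_MIN_TUMOR_CELLS,
        n_tumor_viable=core.n_tumor_viable,
    )


def categorize(value: float, scheme: str) -> str:
    """Tri-categorical therapy-relevant label for a score value.

    CPS: negative [0,1), low [1,20), high [20,100].
    TPS: negative [0,1), low [1,50), high [50,100].
    Threshold values map to the upper category.
    """
    bounds = _scheme_bounds(scheme)
    if not 0.0 <= value <= 100.0:
        raise ScoringError(f"score value must lie in [0, 100], got {value}")
    low, high = bounds
    if value < low:
        return "negative"
    if value < high:
        return "low"
    return "high"


def aggregate_lesion(
    cores: list[PDL1Score],
    lesion_id: str = "",
    lesion_type: str = "primary",
    treated: bool = False,
) -> LesionScore:
    """Aggregate core scores to a lesion score (mean over QC-passing cores).

    With a single QC-passing core the lesion takes that core's value; with
    none the lesion is flagged excluded (``score is None``).
    """
    if not cores:
        raise ScoringError(f"lesion {lesion_id!r}: no cores to aggregate")
    passing = [c for c in cores if c.qc_pass]
    if not passing:
        return LesionScore(lesion_id, lesion_type, treated, None, list(cores))
    agg = PDL1Score(
        cps=float(np.mean([c.cps for c in passing])),
        tps=float(np.mean([c.tps for c in passing])),
        cps_raw=float(np.mean([c.cps_raw for c in passing])),
        qc_pass=True,
        n_tumor_viable=int(sum(c.n_tumor_viable for c in passing)),
    )
    return LesionScore(lesion_id, lesion_type, treated, agg, list(cores))


# ---------------------------------------------------------------------------
# Table (DataFrame) interface used by the pipeline


def _scheme_bounds(scheme: str) -> tuple[float, float]:
    try:
        return CATEGORY_BOUNDS[scheme.upper()]
    except KeyError:
        raise ScoringError(f"unknown scheme {scheme!r}; expected CPS or TPS") from None


def categorize_series(values: pd.Series | np.ndarray, scheme: str) -> pd.Series:
    """Vectorized :func:`categorize`."""
    low, high = _scheme_bounds(scheme)
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 100)):
        raise ScoringError("score values must lie in [0, 100]")
    out = np.where(v >= high, "high", np.where(v >= low, "low", "negative"))
    return pd.Series(out, index=getattr(values, "index", None), dtype="object")


def score_cores(cores: pd.DataFrame) -> pd.DataFrame:
    """Score a per-core counts table.

    Expects columns ``n_tumor_viable``, ``n_tumor_pos``, ``n_immune_pos``
    (identifier/metadata columns are passed through). Adds ``cps``, ``tps``,
    ``cps_raw``, ``qc_pass``, ``category_cps``, ``category_tps``.
    """
    required = {"n_tumor_viable", "n_tumor_pos", "n_immune_pos"}
    missing = sorted(required - set(cores.columns))
    if missing:
        raise ScoringError(f"counts table lacks columns: {missing}")
    if (cores["n_tumor_viable"] == 0).any():
        bad = cores.index[cores["n_tumor_viable"] == 0].tolist()
        raise UndefinedScoreError(f"zero viable tumor cells in rows {bad[:5]}")
    if (cores[list(required)] < 0).any().any():
        raise ScoringError("negative cell counts in counts table")
    if (cores["n_tumor_pos"] > cores["n_tumor_viable"]).any():
        raise ScoringError("n_tumor_pos exceeds n_tumor_viable in counts table")

    out = cores.copy()
    n = out["n_tumor_viable"].astype(float)
    out["tps"] = 100.0 * out["n_tumor_pos"] / n
    out["cps_raw"] = 100.0 * (out["n_tumor_pos"] + out["n_immune_pos"]) / n
    out["cps"] = out["cps_raw"].clip(upper=100.0)
    out["qc_pass"] = out["n_tumor_viable"] >= QC_MIN_TUMOR_CELLS
    out["category_cps"] = categorize_series(out["cps"], "CPS")
    out["category_tps"] = categorize_series(out["tps"], "TPS")
    return out


def aggregate_lesions(scored_cores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a scored per-core table to one row per lesion.

    Means are taken over QC-passing cores only. Lesions with no passing
    core appear with ``excluded=True`` and NaN scores so that callers can
    report them; downstream analyses drop them.
    """
    meta_cols = [
        c
        for c in ("patient_id", "lesion_type", "treated")
        if c in scored_cores.columns
    ]
    grouped = scored_cores.groupby("lesion_id", sort=True)
    meta = grouped[meta_cols].first() if meta_cols else pd.DataFrame(index=grouped.size().index)

    passing = scored_cores[scored_cores["qc_pass"]]
    means = passing.groupby("lesion_id")[["cps", "tps", "cps_raw"]].mean()

    lesions = meta.join(means, how="left")
    lesions["n_cores"] = grouped.size()
    lesions["n_cores_qc"] = (
        passing.groupby("lesion_id").size().reindex(lesions.index).fillna(0).astype(int)
    )
    lesions["excluded"] = lesions["n_cores_qc"] == 0
    ok = ~lesions["excluded"]
    lesions["category_cps"] = pd.Series(pd.NA, index=lesions.index, dtype="object")
    lesions["category_tps"] = pd.Series(pd.NA, index=lesions.index, dtype="object")
    lesions.loc[ok, "category_cps"] = categorize_series(lesions.loc[ok, "cps"], "CPS")
    lesions.loc[ok, "category_tps"] = categorize_series(lesions.loc[ok, "tps"], "TPS")
    return lesions.reset_index()
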