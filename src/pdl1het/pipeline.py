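"""End-to-end pipeline: simulate/read -> score -> heterogeneity -> survival.

``run_pipeline`` ties the stages together, writes every output table as
CSV (plus Sankey-ready JSON for the transition tables) and records a run
manifest with the seed, a configuration hash, per-stage record counts and
content hashes of the outputs, so a rerun with identical inputs can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import SimulationConfig, generate_cohort, calibration_report
from .heterogeneity import (
    HeterogeneityError,
    inter_tumoral_discordance,
    intra_tumoral_reclassification,
)
from .io import read_core_counts, read_patients, write_table
from .outcomes import OutcomesError, cox_table_by_site, km_logrank, response_association
from .scoring import aggregate_lesions, score_cores

__all__ = ["RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)

SCHEMES = ("CPS", "TPS")
INTER_COMPARISONS = (
    ("primary", "lymph_node_met"),
    ("primary", "local_recurrence"),
    ("primary", "distant_met"),
)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int | None
    config_hash: str
    version: str = __version__
    inputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    cores_path: str | Path | None = None,
    patients_path: str | Path | None = None,
    dialect: str = "tallies",
) -> RunManifest:
    """Run every stage and write the result tables under ``out_dir``.

    Either ``config`` (simulate a cohort) or ``cores_path`` (read detected
    cell tallies, optionally with a patient table for survival) must be
    given. Stage failures that reflect absent data (e.g. no patient with
    a given lesion-type pair) are logged and skipped; schema violations
    raise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config is not None:
        config_repr = json.dumps(config.to_dict(), sort_keys=True, default=str)
        cores, patients = generate_cohort(config)
        seed = config.seed
        inputs = {"simulated": True}
        write_table(cores, out / "cores.csv")
        write_table(patients, out / "patients.csv")
    elif cores_path is not None:
        cores = read_core_counts(cores_path, dialect=dialect)
        patients = read_patients(patients_path) if patients_path else None
        config_repr = f"inputs:{cores_path}:{patients_path}"
        seed = None
        inputs = {"cores": str(cores_path), "patients": str(patients_path)}
    else:
        raise ValueError("run_pipeline needs a simulation config or a cores table path")

    manifest = RunManifest(
        seed=seed,
        config_hash=hashlib.sha256(config_repr.encode()).hexdigest()[:16],
        inputs=inputs,
    )

    # --- scoring
    scored = score_cores(cores)
    lesions = aggregate_lesions(scored)
    usable = lesions[~lesions["excluded"]]
    write_table(_round_scores(scored), out / "scores_per_core.csv")
    write_table(_round_scores(lesions), out / "scores_per_lesion.csv")
    manifest.counts.update(
        cores_read=int(len(scored)),
        cores_failing_qc=int((~scored["qc_pass"]).sum()),
        lesions_total=int(len(lesions)),
        lesions_analyzed=int(len(usable)),
    )

    if len(cores) == 0:
        _write_manifest(manifest, out)
        return manifest

    # --- intra-tumoral reclassification (untreated primaries and recurrences)
    pairs_compared = 0
    test_rows = []
    for scheme in SCHEMES:
        for lesion_type, label in (("primary", "primary_untreated"), ("local_recurrence", "local_recurrence")):
            mask = scored["lesion_type"] == lesion_type
            if lesion_type == "primary":
                mask &= ~scored["treated"].astype(bool)
            table, pairs = intra_tumoral_reclassification(scored[mask], scheme)
            stem = f"reclassification_intra_{label}_{scheme.lower()}"
            write_table(table.to_frame().reset_index(), out / f"{stem}.csv")
            (out / f"{stem}.json").write_text(json.dumps(table.sankey(), indent=2))
            pairs_compared += table.n_pairs
            test_rows.append(
                {
                    "analysis": f"intra_{label}",
                    "scheme": scheme,
                    "n_pairs": table.n_pairs,
                    "reclassification_rate": table.reclassification_rate,
                }
            )

    # --- inter-tumoral discordance
    for scheme in SCHEMES:
        for type_a, type_b in INTER_COMPARISONS:
            try:
                table, pairs, test = inter_tumoral_discordance(usable, type_a, type_b, scheme)
            except HeterogeneityError as exc:
                logger.info("inter-tumoral %s vs %s (%s): skipped (%s)", type_a, type_b, scheme, exc)
                continue
            stem = f"discordance_{type_a}_vs_{type_b}_{scheme.lower()}"
            write_table(table.to_frame().reset_index(), out / f"{stem}.csv")
            pairs_compared += table.n_pairs
            test_rows.append(
                {
                    "analysis": f"inter_{type_a}_vs_{type_b}",
                    "scheme": scheme,
                    "n_pairs": table.n_pairs,
                    "reclassification_rate": table.reclassification_rate,
                    "wilcoxon_statistic": test.statistic,
                    "wilcoxon_p": test.p_value,
                }
            )
    write_table(pd.DataFrame(test_rows), out / "heterogeneity_tests.csv")
    manifest.counts["pairs_compared"] = int(pairs_compared)

    # --- survival and associations (need the patient table)
    if patients is not None and "os_months" in patients.columns:
        _survival_stage(patients, usable, out)
        manifest.counts["patients_analyzed"] = int(len(patients))

    write_table(calibration_report(cores), out / "calibration_report.csv")

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest.output_hashes[f.name] = _hash_file(f)
    _write_manifest(manifest, out)
    return manifest


def _survival_stage(patients: pd.DataFrame, usable_lesions: pd.DataFrame, out: Path) -> None:
    rows, curves = [], []
    for scheme in ("cps", "tps"):
        for lesion_type in ("primary", "local_recurrence", "lymph_node_met"):
            sub = usable_lesions[usable_lesions["lesion_type"] == lesion_type]
            means = sub.groupby("patient_id")[scheme].mean()
            merged = patients.merge(means.rename(scheme), on="patient_id", how="inner")
            if merged.empty:
                continue
            try:
                res, curve = km_logrank(merged, value_col=scheme)
            except OutcomesError as exc:
                logger.info("survival %s/%s skipped: %s", lesion_type, scheme, exc)
                continue
            curve["lesion_type"] = lesion_type
            curve["scheme"] = scheme.upper()
            curves.append(curve)
            rows.append(
                {
                    "lesion_type": lesion_type,
                    "scheme": scheme.upper(),
                    "model": res.model,
                    "hr": res.hr,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "logrank_p": res.p_value,
                    "status": res.status,
                    **{f"n[{k}]": v for k, v in res.n_by_group.items()},
                    **{f"median_os[{k}]": v for k, v in res.median_os_by_group.items()},
                }
            )
        # site-stratified Cox tables use the primary-lesion score
        pri = usable_lesions[usable_lesions["lesion_type"] == "primary"]
        means = pri.groupby("patient_id")[scheme].mean()
        merged = patients.merge(means.rename(scheme), on="patient_id", how="inner")
        if not merged.empty:
            tab = cox_table_by_site(merged, value_col=scheme)
            tab.insert(0, "scheme", scheme.upper())
            write_table(tab, out / f"cox_by_site_{scheme}.csv")

        if "response" in patients.columns and not merged.empty:
            rc = merged[merged.get("treatment", pd.Series(index=merged.index, dtype=object)) == "radiochemo"]
            assoc = response_association(rc, value_col=scheme)
            write_table(
                pd.DataFrame(
                    [
                        {
                            "scheme": scheme.upper(),
                            "contingency_coefficient": assoc.coefficient,
                            "chi2": assoc.chi2,
                            "p_value": assoc.p_value,
                            "n": assoc.n,
                            "status": assoc.status,
                        }
                    ]
                ),
                out / f"response_association_{scheme}.csv",
            )
    if rows:
        write_table(pd.DataFrame(rows), out / "survival_results.csv")
    if curves:
        write_table(pd.concat(curves, ignore_index=True), out / "km_curves.csv")


def _round_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Round score columns to one decimal for reports (full precision stays
    internal)."""
    out = df.copy()
    for col in ("cps", "tps", "cps_raw"):
        if col in out.columns:
            out[col] = out[col].astype(float).round(1)
    return out


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    (out / "manifest.json").write_text(manifest.to_json())
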