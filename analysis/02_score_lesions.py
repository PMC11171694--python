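"""Score every core, aggregate to lesions, and tabulate category frequencies.

Writes the per-core and per-lesion score tables and a per-lesion-type
summary of CPS/TPS positivity (>=1), high expression (>=20 CPS / >=50
TPS) and medians — the cohort's expression profile.
"""

from pathlib import Path

from pdl1het.cohort import calibration_report
from pdl1het.io import read_core_counts, write_table
from pdl1het.scoring import aggregate_lesions, score_cores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cores = read_core_counts(ROOT / "cohort" / "cores.csv")
    scored = score_cores(cores)
    lesions = aggregate_lesions(scored)
    write_table(scored, ROOT / "scores_per_core.csv")
    write_table(lesions, ROOT / "scores_per_lesion.csv")

    n_fail = int((~scored["qc_pass"]).sum())
    print(f"scored {len(scored)} cores ({n_fail} below the 100-cell QC threshold), "
          f"{len(lesions)} lesions ({int(lesions['excluded'].sum())} excluded)")

    summary = calibration_report(cores)
    write_table(summary, ROOT / "expression_by_lesion_type.csv")
    print("\nexpression by lesion type (lesion-level, % of lesions):")
    print(summary.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
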