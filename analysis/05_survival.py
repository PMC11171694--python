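"""Five-year overall survival by PD-L1 positivity, per lesion type.

Kaplan-Meier curves with log-rank tests for CPS/TPS >= 1 vs < 1 in
primary tumors, local recurrences and lymph-node metastases
(administrative censoring at 60 months), followed by uni- and
multivariate Cox tables for the whole cohort and the oropharyngeal /
oral-cavity subsites (stage- and, for the oropharynx, p16-adjusted).
"""

from pathlib import Path

from pdl1het.io import read_core_counts, read_patients, write_table
from pdl1het.outcomes import cox_table_by_site, km_logrank
from pdl1het.scoring import aggregate_lesions, score_cores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lesions = aggregate_lesions(score_cores(read_core_counts(ROOT / "cohort" / "cores.csv")))
    patients = read_patients(ROOT / "cohort" / "patients.csv")
    usable = lesions[~lesions["excluded"]]
    out = ROOT / "survival"

    for scheme in ("cps", "tps"):
        for lesion_type in ("primary", "local_recurrence", "lymph_node_met"):
            sub = usable[usable["lesion_type"] == lesion_type]
            means = sub.groupby("patient_id")[scheme].mean()
            merged = patients.merge(means.rename(scheme), on="patient_id", how="inner")
            res, curves = km_logrank(merged, value_col=scheme)
            write_table(curves, out / f"km_{lesion_type}_{scheme}.csv")
            med = {k: f"{v:.1f}" for k, v in res.median_os_by_group.items()}
            print(
                f"{lesion_type} [{scheme.upper()} >=1 vs <1]: n={res.n_by_group}, "
                f"median OS {med}, HR {res.hr:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f}), "
                f"log-rank p = {res.p_value:.4f}"
            )

        pri = usable[usable["lesion_type"] == "primary"]
        means = pri.groupby("patient_id")[scheme].mean()
        merged = patients.merge(means.rename(scheme), on="patient_id", how="inner")
        tab = cox_table_by_site(merged, value_col=scheme)
        write_table(tab, out / f"cox_by_site_{scheme}.csv")
        print(f"\nCox table [{scheme.upper()}]:")
        print(tab.round(3).to_string(index=False))
        print()


if __name__ == "__main__":
    main()
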