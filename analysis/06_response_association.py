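"""Association of PD-L1 positivity with radio(chemo)therapy response.

For patients whose primary tumor was treated with radiochemotherapy,
relates binary CPS/TPS positivity (>= 1) of the primary lesion to the
dichotomized RECIST response through the contingency coefficient on the
2x2 table — the subgroup is too small for logistic regression.
"""

from pathlib import Path

import pandas as pd

from pdl1het.io import read_core_counts, read_patients, write_table
from pdl1het.outcomes import response_association
from pdl1het.scoring import aggregate_lesions, score_cores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lesions = aggregate_lesions(score_cores(read_core_counts(ROOT / "cohort" / "cores.csv")))
    patients = read_patients(ROOT / "cohort" / "patients.csv")
    pri = lesions[(~lesions["excluded"]) & (lesions["lesion_type"] == "primary")]
    rows = []
    for scheme in ("cps", "tps"):
        means = pri.groupby("patient_id")[scheme].mean()
        merged = patients.merge(means.rename(scheme), on="patient_id", how="inner")
        rc = merged[merged["treatment"] == "radiochemo"]
        res = response_association(rc, value_col=scheme)
        rows.append(
            {"scheme": scheme.upper(), "contingency_coefficient": res.coefficient,
             "chi2": res.chi2, "p_value": res.p_value, "n": res.n, "status": res.status}
        )
        print(
            f"{scheme.upper()} >= 1 vs RECIST response (n={res.n} radiochemo patients): "
            f"C = {res.coefficient:.2f}, p = {res.p_value:.2f} [{res.status}]"
        )
    write_table(pd.DataFrame(rows), ROOT / "response_association.csv")


if __name__ == "__main__":
    main()
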