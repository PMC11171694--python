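"""Inter-tumoral discordance: primary tumor vs metastases and recurrences.

Pairs each patient's primary-lesion mean score with the mean score of the
same patient's lymph-node metastases, local recurrences and distant
metastases; reports category discordance rates, the paired Wilcoxon test
on absolute values, and Spearman correlations of the paired scores.
"""

from pathlib import Path

import numpy as np

from pdl1het.heterogeneity import HeterogeneityError, correlate, inter_tumoral_discordance
from pdl1het.io import read_core_counts, write_table
from pdl1het.scoring import aggregate_lesions, score_cores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lesions = aggregate_lesions(score_cores(read_core_counts(ROOT / "cohort" / "cores.csv")))
    out = ROOT / "intertumoral"
    for type_b in ("lymph_node_met", "local_recurrence", "distant_met"):
        for scheme in ("CPS", "TPS"):
            try:
                table, pairs, test = inter_tumoral_discordance(lesions, "primary", type_b, scheme)
            except HeterogeneityError as exc:
                print(f"primary vs {type_b} [{scheme}]: skipped ({exc})")
                continue
            stem = f"discordance_primary_vs_{type_b}_{scheme.lower()}"
            write_table(table.to_frame().reset_index(), out / f"{stem}.csv")
            ref = np.array([p.reference_value for p in pairs])
            comp = np.array([p.comparison_value for p in pairs])
            rho = correlate(ref, comp, "spearman")
            rho_txt = f"{rho.coefficient:.2f}" if rho.defined else "undefined"
            print(
                f"primary vs {type_b} [{scheme}]: {table.n_pairs} patients, "
                f"{100 * table.reclassification_rate:.1f}% discordant, "
                f"wilcoxon p = {test.p_value:.3f}, spearman rho = {rho_txt}"
            )


if __name__ == "__main__":
    main()
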