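"""Intra-tumoral reclassification: does a second core change the category?

For untreated primary tumors and for local recurrences, compares the two
cores of each lesion (first core = reference) on the tri-categorical
CPS/TPS scale, writes 3x3 transition tables plus Sankey-ready JSON, and
reports the reclassification rate and where reference-negative lesions
moved — the clinically critical direction (a negative single biopsy that
a second sample upgrades to low/high would change therapy eligibility).
"""

import json
from pathlib import Path

from pdl1het.heterogeneity import intra_tumoral_reclassification
from pdl1het.io import read_core_counts, write_table
from pdl1het.scoring import score_cores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scored = score_cores(read_core_counts(ROOT / "cohort" / "cores.csv"))
    out = ROOT / "intratumoral"
    for label, mask in (
        ("primary_untreated", (scored["lesion_type"] == "primary") & (~scored["treated"])),
        ("local_recurrence", scored["lesion_type"] == "local_recurrence"),
    ):
        for scheme in ("CPS", "TPS"):
            table, _ = intra_tumoral_reclassification(scored[mask], scheme)
            stem = f"reclassification_{label}_{scheme.lower()}"
            write_table(table.to_frame().reset_index(), out / f"{stem}.csv")
            write_table(table.source_breakdown(), out / f"{stem}_breakdown.csv")
            (out / f"{stem}.json").write_text(json.dumps(table.sankey(), indent=2))
            neg = table.counts[0]
            print(
                f"{label} [{scheme}]: {table.n_pairs} pairs, "
                f"{100 * table.reclassification_rate:.1f}% reclassified; "
                f"of {neg.sum()} reference-negative lesions, "
                f"{neg[1]} moved to low and {neg[2]} to high"
            )


if __name__ == "__main__":
    main()
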