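"""Expression patterns associated with RAS-pathway mutations.

Runs the moderated-t differential expression of all probes against RAS-RAF
mutation status and the interior-percentile Fisher threshold scan on the
RAS-linked probes (SPRED2, DUSP6, DKK1, ETV5, COBLL1).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tc6mm import assoc, exprscan, synth

ROOT = Path(__file__).resolve().parents[1] / "results"
SCAN_PROBES = ["SPRED2_1", "DUSP6_1", "DKK1_1", "ETV5_1", "COBLL1_1"]


def main() -> None:
    cohort = synth.read_cohort(ROOT / "fixtures")
    truth = cohort.truth.set_index("sample_id")
    tumor = [s for s in truth.index if truth.at[s, "subgroup"] != "NPC"]
    filtered = assoc.filter_variants(cohort.alterations)
    ras = set(filtered.loc[filtered["gene"].isin(assoc.RAS_RAF_GENES),
                           "sample_id"])
    expr = cohort.expression[tumor]
    group = np.array([s in ras for s in tumor]).astype(int)

    de = exprscan.moderated_t(expr, group)
    de_out = ROOT / "differential_expression.tsv"
    de.table.sort_values("adj_p").to_csv(de_out, sep="\t",
                                         float_format="%.4g")
    top = de.table.nsmallest(8, "adj_p")
    print(f"wrote {de_out} (prior df {de.prior_df:.1f})")
    print("top probes by adjusted p:")
    print(top[["lfc", "t", "adj_p"]].to_string(float_format="%.3g"))

    rows = []
    for probe in SCAN_PROBES:
        res = exprscan.threshold_scan(expr.loc[probe], group, probe=probe)
        rows.append({"probe": probe, "threshold": res.best_threshold,
                     "p": res.best_p, "p_adjusted": res.p_adjusted,
                     "significant": res.significant,
                     "pct_mutated_above": 100 * res.prop_above,
                     "pct_mutated_below": 100 * res.prop_below,
                     "direction": res.direction})
    scan = pd.DataFrame(rows)
    scan_out = ROOT / "threshold_scan.tsv"
    scan.to_csv(scan_out, sep="\t", index=False, float_format="%.4g")
    print(f"\nwrote {scan_out}")
    print(scan.to_string(index=False, float_format=lambda x: f"{x:.3g}"))


if __name__ == "__main__":
    main()
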