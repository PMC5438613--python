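"""Alteration rates by disease stage with trend tests.

Filters the panel calls (VAF >= 5%, RAS hotspots only), resolves
co-occurring RAS-RAF calls to the highest-VAF one, and tests each gene for
a trend in alteration rate over the ordered stages untreated -> in
treatment -> relapse (Cochran-Armitage), plus relapse vs prior stages
(Fisher).
"""

from pathlib import Path

import pandas as pd

from tc6mm import assoc, synth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = synth.read_cohort(ROOT / "fixtures")
    filtered = assoc.resolve_ras_raf(assoc.filter_variants(cohort.alterations))
    truth = cohort.truth.set_index("sample_id")
    clin = cohort.clinical.set_index("sample_id")
    tumor = [s for s in truth.index if truth.at[s, "subgroup"] != "NPC"]
    clin = clin.loc[tumor]

    rows = []
    for gene in sorted(filtered["gene"].unique()):
        mutated = set(filtered.loc[filtered["gene"] == gene, "sample_id"])
        counts, totals = [], []
        for stage in synth.STAGES:
            ids = clin.index[clin["stage"] == stage]
            counts.append(sum(s in mutated for s in ids))
            totals.append(len(ids))
        trend = assoc.cochran_armitage(counts, totals)
        relapse_k, prior_k = counts[2], counts[0] + counts[1]
        relapse_n, prior_n = totals[2], totals[0] + totals[1]
        fisher = assoc.fisher_2x2(
            [[relapse_k, relapse_n - relapse_k],
             [prior_k, prior_n - prior_k]])
        rows.append({
            "gene": gene, "n_altered": len(mutated),
            **{f"rate_{st}": k / n for st, k, n in
               zip(synth.STAGES, counts, totals)},
            "trend_p": trend.p_two_sided,
            "relapse_vs_prior_p": fisher.p_two_sided,
        })
    table = pd.DataFrame(rows).sort_values("trend_p")
    out = ROOT / "mutation_by_stage.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.4g")
    print(f"wrote {out}")
    print("genes with a stage trend at p < 0.05:")
    print(table.loc[table["trend_p"] < 0.05,
                    ["gene", "n_altered", "trend_p"]].to_string(index=False))


if __name__ == "__main__":
    main()
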