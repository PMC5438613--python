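"""Per-gene alteration enrichment across TC-6 subgroup partitions.

For each panel gene (and the Q61/G12-G13 RAS codon classes) finds the
most- vs least-affected subgroup partition and reports the Fisher exact
contrast — the synthetic counterpart of the subgroup-by-alteration table.
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from tc6mm import assoc, synth, tc6

ROOT = Path(__file__).resolve().parents[1] / "results"


def best_partition(filtered, calls, gene, codon=None):
    """Greedy: order subgroups by rate, split at the largest contrast."""
    usable = calls[calls["subgroup"] != tc6.NPC_LABEL]
    hits = filtered[filtered["gene"] == gene]
    if codon is not None:
        hits = hits[hits["codon"].isin(codon)]
    mutated = set(hits["sample_id"])
    rates = {}
    for sg, ids in usable.groupby("subgroup")["sample_id"]:
        if len(ids) >= 10:
            rates[sg] = sum(s in mutated for s in ids) / len(ids)
    ordered = sorted(rates, key=rates.get, reverse=True)
    best = None
    for k in range(1, len(ordered)):
        part = (tuple(ordered[:k]), tuple(ordered[k:]))
        res = assoc.subgroup_enrichment(filtered, usable, gene, part,
                                        codon=None)
        if codon is not None:
            # rebuild with the codon restriction at sample level
            in_a = usable.loc[usable["subgroup"].isin(part[0]), "sample_id"]
            in_b = usable.loc[usable["subgroup"].isin(part[1]), "sample_id"]
            a = sum(s in mutated for s in in_a)
            c = sum(s in mutated for s in in_b)
            res = assoc.fisher_2x2([[a, len(in_a) - a], [c, len(in_b) - c]])
        if best is None or res.p_two_sided < best[1].p_two_sided:
            best = (part, res)
    return best


def main() -> None:
    cohort = synth.read_cohort(ROOT / "fixtures")
    calls = pd.read_csv(ROOT / "subgroup_calls.tsv", sep="\t")
    filtered = assoc.resolve_ras_raf(assoc.filter_variants(cohort.alterations))

    targets = [("NRAS", ("Q61",)), ("NRAS", ("G12", "G13")),
               ("KRAS", ("Q61",)), ("KRAS", ("G12", "G13")),
               ("BRAF", None)]
    targets += [(g, None) for g in sorted(set(filtered["gene"]))
                if g not in ("NRAS", "KRAS", "BRAF")]
    rows = []
    for gene, codon in targets:
        found = best_partition(filtered, calls, gene, codon)
        if found is None:
            continue
        (top, rest), res = found
        label = gene if codon is None else f"{gene} {'/'.join(codon)}"
        rows.append({"alteration": label,
                     "most_common": "+".join(top),
                     "least_common": "+".join(rest),
                     "odds_ratio": res.odds_ratio,
                     "fisher_p": res.p_two_sided})
    table = pd.DataFrame(rows)
    out = ROOT / "subgroup_enrichment.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.4g")
    print(f"wrote {out}")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
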