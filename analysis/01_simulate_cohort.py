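"""Generate the default synthetic cohort used by the downstream analyses.

Writes an 805-sample cohort (plus normal-plasma-cell controls) with the
default subgroup mix, stage mix, per-subgroup/stage alteration rates, and
planted survival structure to results/fixtures/.
"""

from pathlib import Path

from tc6mm import synth

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = 1


def main() -> None:
    cohort = synth.generate_cohort(n_samples=805, seed=SEED)
    paths = synth.write_fixtures(cohort, OUT)
    tumor = cohort.truth[cohort.truth["subgroup"] != "NPC"]
    print(f"wrote {len(paths)} tables to {OUT}")
    print(f"samples: {len(cohort.sample_ids)} ({len(tumor)} tumor, "
          f"{cohort.config.n_npc} NPC controls)")
    print("subgroup mix:")
    print(tumor["subgroup"].value_counts().to_string())
    print(f"alteration calls: {len(cohort.alterations)} "
          f"(RAS-RAF mutated fraction {tumor['rasraf_mut'].mean():.3f})")


if __name__ == "__main__":
    main()
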