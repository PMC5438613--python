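import pandas as pd
import pytest

from tc6mm import synth, tc6


@pytest.fixture(scope="session")
def cohort900() -> synth.SyntheticCohort:
    """Clean synthetic cohort: 900 tumor samples + NPC controls, seed 1."""
    return synth.generate_cohort(n_samples=900, seed=1)


@pytest.fixture(scope="session")
def classified900(cohort900):
    """Rule labels, trained TC-6 model, and classifier calls on cohort900."""
    c = cohort900
    panel = tc6.DEFAULT_PANEL
    npc_ids = c.truth.loc[c.truth["subgroup"] == "NPC", "sample_id"]
    centroid = c.expression.loc[list(panel.all_probes), list(npc_ids)].mean(axis=1)
    rules = tc6.rule_label(c.expression, panel, npc_centroid=centroid, seed=1)
    model = tc6.train(
        c.expression, rules.set_index("sample_id")["subgroup"], panel, seed=1
    )
    calls = tc6.classify(model, c.expression)
    return rules, model, calls


@pytest.fixture(scope="session")
def cohort5000() -> synth.SyntheticCohort:
    """Large cohort where discrete-test asymptotics (uniform null p) hold."""
    return synth.generate_cohort(n_samples=5000, seed=21)


@pytest.fixture(scope="session")
def tumor_truth(cohort900) -> pd.Series:
    truth = cohort900.truth.set_index("sample_id")
    return truth.loc[truth["subgroup"] != "NPC", "subgroup"]


@pytest.fixture(scope="session")
def filtered_alterations(cohort900) -> pd.DataFrame:
    from tc6mm import assoc

    return assoc.resolve_ras_raf(assoc.filter_variants(cohort900.alterations))
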