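"""Synthetic myeloma cohort generator.

Emulates the statistical structure the analysis assumes so every stage of
the pipeline is testable without access to patient data: TC-6 subgroup
expression spikes on the log2 scale, subgroup- and disease-stage-dependent
mutation rates for the targeted panel genes, RAS-pathway-linked expression
programs (DUSP6/SPRED2/DKK1/ETV5 up, COBLL1 down, NFκB index down outside
MAF), planted GEP70 risk structure, adverse-alteration expression signatures
(FAF1-low with CDKN2C deletion, CDKN2C-high with RB1 alteration), and a
proportional-hazards survival layer with independent exponential censoring.

Default rates are the cohort conditions reported for the real data set
(subgroup mix, stage mix, per-subgroup and per-stage alteration rates); they
are configuration, not tuning knobs. Expression probes within a sample are
independent given the sample's labels — real microarray covariance is not
simulated (see the methods note for what that implies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as em
from .tc6 import DEFAULT_PANEL, SUBGROUPS
from .signatures import (
    DEFAULT_GEP70_DOWN,
    DEFAULT_GEP70_UP,
    DEFAULT_NFKB_PROBES,
    DEFAULT_PROLIF_PROBES,
)

__all__ = [
    "CohortConfig",
    "SurvivalParams",
    "SpikeParams",
    "SyntheticCohort",
    "generate_cohort",
    "write_fixtures",
    "read_cohort",
    "DEFAULT_SUBGROUP_PROPORTIONS",
    "DEFAULT_MUTATION_RATES",
    "RAS_CLASSES",
    "ADVERSE_GENES",
]

STAGES = ("untreated", "in_treatment", "relapse")

DEFAULT_SUBGROUP_PROPORTIONS = {
    "D1-HRD": 0.331,
    "D2": 0.262,
    "CCND1-11q13": 0.183,
    "CCND3-6p21": 0.019,
    "MMSET": 0.142,
    "MAF": 0.063,
}

#: (gene, codon class) -> per-subgroup alteration probability. RAS classes
#: are drawn separately so codon-level contrasts are planted directly.
DEFAULT_MUTATION_RATES: dict[tuple[str, str | None], dict[str, float]] = {
    ("NRAS", "Q61"): {"D1-HRD": 0.235, "D2": 0.123, "CCND1-11q13": 0.209,
                      "CCND3-6p21": 0.150, "MMSET": 0.022, "MAF": 0.021},
    ("NRAS", "G12/G13"): {"D1-HRD": 0.027, "D2": 0.027, "CCND1-11q13": 0.027,
                          "CCND3-6p21": 0.030, "MMSET": 0.058, "MAF": 0.058},
    ("KRAS", "Q61"): {"D1-HRD": 0.090, "D2": 0.090, "CCND1-11q13": 0.090,
                      "CCND3-6p21": 0.090, "MMSET": 0.058, "MAF": 0.058},
    ("KRAS", "G12/G13"): {"D1-HRD": 0.078, "D2": 0.078, "CCND1-11q13": 0.078,
                          "CCND3-6p21": 0.078, "MMSET": 0.078, "MAF": 0.146},
    ("BRAF", "V600E"): {"D1-HRD": 0.026, "D2": 0.026, "CCND1-11q13": 0.026,
                        "CCND3-6p21": 0.026, "MMSET": 0.051, "MAF": 0.051},
    ("TP53", None): {"D1-HRD": 0.134, "D2": 0.093, "CCND1-11q13": 0.134,
                     "CCND3-6p21": 0.100, "MMSET": 0.093, "MAF": 0.134},
    ("TRAF3", None): {"D1-HRD": 0.014, "D2": 0.092, "CCND1-11q13": 0.014,
                      "CCND3-6p21": 0.050, "MMSET": 0.092, "MAF": 0.092},
    ("FGFR3", None): {"D1-HRD": 0.0, "D2": 0.0, "CCND1-11q13": 0.0,
                      "CCND3-6p21": 0.0, "MMSET": 0.281, "MAF": 0.0},
    ("RB1", None): {"D1-HRD": 0.032, "D2": 0.069, "CCND1-11q13": 0.032,
                    "CCND3-6p21": 0.032, "MMSET": 0.069, "MAF": 0.032},
    ("CDKN2C", None): {"D1-HRD": 0.015, "D2": 0.066, "CCND1-11q13": 0.015,
                       "CCND3-6p21": 0.015, "MMSET": 0.066, "MAF": 0.015},
    ("BIRC3", None): {"D1-HRD": 0.014, "D2": 0.014, "CCND1-11q13": 0.014,
                      "CCND3-6p21": 0.014, "MMSET": 0.146, "MAF": 0.014},
    ("DNMT3A", None): {"D1-HRD": 0.011, "D2": 0.039, "CCND1-11q13": 0.039,
                       "CCND3-6p21": 0.030, "MMSET": 0.039, "MAF": 0.011},
    ("ATM", None): {"D1-HRD": 0.030, "D2": 0.030, "CCND1-11q13": 0.030,
                    "CCND3-6p21": 0.030, "MMSET": 0.088, "MAF": 0.088},
    ("TET2", None): {"D1-HRD": 0.022, "D2": 0.041, "CCND1-11q13": 0.022,
                     "CCND3-6p21": 0.022, "MMSET": 0.022, "MAF": 0.041},
}

#: per-stage multiplicative rate factors (untreated, in_treatment, relapse),
#: fit from the stage columns of the alteration-by-stage table
DEFAULT_STAGE_MULTIPLIERS: dict[tuple[str, str | None], tuple[float, float, float]] = {
    ("NRAS", "Q61"): (0.81, 0.83, 1.32),
    ("NRAS", "G12/G13"): (0.50, 1.03, 1.28),
    ("KRAS", "Q61"): (0.65, 0.98, 1.25),
    ("TP53", None): (0.58, 0.86, 1.50),
    ("RB1", None): (0.57, 0.91, 1.38),
    ("CDKN2C", None): (0.44, 0.83, 1.50),
}

RAS_CLASSES = (("KRAS", "G12/G13"), ("KRAS", "Q61"), ("NRAS", "G12/G13"),
               ("NRAS", "Q61"), ("BRAF", "V600E"))
ADVERSE_GENES = ("TP53", "CDKN2C", "RB1")

#: fraction of each gene's alterations that are homozygous deletions
DELETION_FRACTION = {"TP53": 0.03, "CDKN2C": 0.79, "RB1": 0.39,
                     "TRAF3": 0.34, "BIRC3": 0.91, "TET2": 0.04}

DEFAULT_GEP70_HR_RATES = {"D1-HRD": 0.094, "D2": 0.127, "CCND1-11q13": 0.067,
                          "CCND3-6p21": 0.059, "MMSET": 0.258, "MAF": 0.456}


@dataclass(frozen=True)
class SurvivalParams:
    """Proportional-hazards layer: h = h0 * hr_adverse^A * hr_gep70^G."""

    baseline_hazard: float = -math.log(0.865) / 18.0  # per month
    hr_adverse: float = 3.5
    hr_gep70: float = 3.5
    censor_rate: float = math.log(2) / 13.5  # median censoring 13.5 months


@dataclass(frozen=True)
class SpikeParams:
    """Two-component spike model on the log2 scale."""

    background: float = 3.5
    shift: float = 6.0  # spike component sits shift log2 units above background

    def __post_init__(self) -> None:
        if self.shift < 4.0:
            raise ValueError("spike separation below 4 log2 units")


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 805
    subgroup_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_PROPORTIONS))
    stage_proportions: tuple[float, float, float] = (0.23, 0.41, 0.36)
    mutation_rates: dict[tuple[str, str | None], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MUTATION_RATES.items()})
    stage_rate_multipliers: dict[tuple[str, str | None], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MULTIPLIERS))
    gep70_hr_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GEP70_HR_RATES))
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    spike_params: SpikeParams = field(default_factory=SpikeParams)
    noise_sd: float = 0.5
    n_npc: int = 20
    n_noise_probes: int = 100
    sub5_call_rate: float = 0.05  # per-sample rate of sub-5%-VAF nuisance calls
    nonactivating_ras_rate: float = 0.02  # e.g. BRAF D594G, dropped by the filter
    mmset_fgfr3_low_frac: float = 0.20
    # conditional RAS-RAF rates in MMSET by FGFR3-low status; None disables
    # the conditioning and leaves the configured per-class rates untouched
    mmset_rasraf_rate_fgfr3_low: float | None = 0.56
    mmset_rasraf_rate_fgfr3_high: float | None = 0.21
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name, props in (("subgroup_proportions", self.subgroup_proportions.values()),
                            ("stage_proportions", self.stage_proportions)):
            total = float(sum(props))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sum to {total}, not 1")
            if any(p < 0 for p in props):
                raise ValueError(f"negative entry in {name}")
        for key, per_sg in self.mutation_rates.items():
            for sg, rate in per_sg.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"rate {rate} for {key}/{sg} outside [0,1]")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # probes x samples, log2
    alterations: pd.DataFrame  # sample_id, gene, alteration_type, codon, vaf
    clinical: pd.DataFrame  # sample_id, stage, os_months, os_event
    truth: pd.DataFrame  # per-sample generating labels
    config: CohortConfig | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def _probe_list(n_noise: int) -> list[str]:
    probes = list(DEFAULT_PANEL.all_probes)
    probes += list(DEFAULT_NFKB_PROBES)
    probes += list(DEFAULT_GEP70_UP) + list(DEFAULT_GEP70_DOWN)
    probes += list(DEFAULT_PROLIF_PROBES)
    probes += ["SPRED2_1", "DKK1_1", "ETV5_1", "COBLL1_1", "RRAS2_1",
               "MS4A1_1", "FAF1_1", "CDKN2C_1"]
    probes += [f"NP{i:04d}" for i in range(1, n_noise + 1)]
    return probes


def _draw_alterations(rng, sample_id, subgroup, stage_idx, cfg: CohortConfig,
                      fgfr3_low: bool) -> tuple[list[dict], set[str]]:
    """Per-sample panel calls; returns (rows, set of truly altered genes)."""
    rows: list[dict] = []
    genes_hit: set[str] = set()

    # MMSET RAS rates are conditioned on FGFR3-low status (locus-loss cases
    # carry RAS mutations far more often)
    ras_scale = 1.0
    conditioned = (cfg.mmset_rasraf_rate_fgfr3_low is not None
                   and cfg.mmset_rasraf_rate_fgfr3_high is not None)
    if subgroup == "MMSET" and conditioned:
        base_any = 1.0
        for key in RAS_CLASSES:
            base_any *= 1.0 - cfg.mutation_rates.get(key, {}).get(subgroup, 0.0)
        base_any = 1.0 - base_any
        target = (cfg.mmset_rasraf_rate_fgfr3_low if fgfr3_low
                  else cfg.mmset_rasraf_rate_fgfr3_high)
        ras_scale = target / base_any if base_any > 0 else 0.0

    drawn: dict[tuple[str, str | None], bool] = {}
    for key, per_sg in cfg.mutation_rates.items():
        gene, codon_class = key
        if gene == "FGFR3":
            continue  # handled after RAS status is known
        p = per_sg.get(subgroup, 0.0)
        mult = cfg.stage_rate_multipliers.get(key)
        if mult is not None:
            p *= mult[stage_idx]
        if key in RAS_CLASSES:
            p *= ras_scale
        drawn[key] = rng.random() < min(max(p, 0.0), 1.0)

    # CDKN2C and RB1 alterations are mutually exclusive paths; on collision
    # the RB1 draw is dropped
    if drawn.get(("CDKN2C", None)) and drawn.get(("RB1", None)):
        drawn[("RB1", None)] = False

    ras_hit = any(drawn.get(k, False) for k in RAS_CLASSES)

    # FGFR3 activating mutations require an intact, expressed locus and are
    # functionally redundant with (hence exclusive of) RAS-RAF mutations
    fgfr3_rate = cfg.mutation_rates.get(("FGFR3", None), {}).get(subgroup, 0.0)
    if subgroup == "MMSET" and fgfr3_rate > 0 and not fgfr3_low and not ras_hit:
        p_high = 1.0 - cfg.mmset_fgfr3_low_frac
        p_no_ras = 1.0 - (cfg.mmset_rasraf_rate_fgfr3_high if conditioned else 0.0)
        denom = p_high * p_no_ras
        p_fgfr3 = fgfr3_rate / denom if denom > 0 else 0.0
        drawn[("FGFR3", None)] = rng.random() < min(p_fgfr3, 1.0)

    for key, hit in drawn.items():
        if not hit:
            continue
        gene, codon_class = key
        genes_hit.add(gene)
        if codon_class == "G12/G13":
            codon = "G12" if rng.random() < 0.7 else "G13"
            alt_type = "missense"
        elif codon_class in ("Q61", "V600E"):
            codon = codon_class
            alt_type = "missense"
        else:
            codon = ""
            del_frac = DELETION_FRACTION.get(gene, 0.0)
            if rng.random() < del_frac:
                alt_type = "deletion"
            elif gene == "FGFR3":
                alt_type = "missense"
            else:
                alt_type = rng.choice(
                    ["missense", "frameshift", "nonsense", "splice"],
                    p=[0.60, 0.20, 0.15, 0.05],
                )
        vaf = 1.0 if alt_type == "deletion" else float(rng.uniform(0.05, 0.6))
        rows.append(dict(sample_id=sample_id, gene=gene,
                         alteration_type=alt_type, codon=codon, vaf=vaf))

    # nuisance calls the variant filter must remove
    if rng.random() < cfg.sub5_call_rate:
        gene = rng.choice(["KRAS", "NRAS", "TP53", "DNMT3A"])
        codon = {"KRAS": "G12", "NRAS": "Q61"}.get(gene, "")
        rows.append(dict(sample_id=sample_id, gene=gene,
                         alteration_type="missense", codon=codon,
                         vaf=float(rng.uniform(0.01, 0.049))))
    if rng.random() < cfg.nonactivating_ras_rate:
        rows.append(dict(sample_id=sample_id, gene="BRAF",
                         alteration_type="missense", codon="D594G",
                         vaf=float(rng.uniform(0.05, 0.3))))
    return rows, genes_hit


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Draw a full synthetic cohort (expression, alterations, clinical, truth).

    Deterministic given the config seed. Keyword overrides are applied to a
    copy of the (default) config, e.g. ``generate_cohort(n_samples=200, seed=3)``.
    """
    cfg = config if config is not None else CohortConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    subgroup_names = list(cfg.subgroup_proportions)
    probs = np.array([cfg.subgroup_proportions[s] for s in subgroup_names])
    subgroups = rng.choice(subgroup_names, size=n, p=probs / probs.sum())
    stages_idx = rng.choice(3, size=n, p=np.asarray(cfg.stage_proportions))

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    npc_ids = [f"N{i:04d}" for i in range(1, cfg.n_npc + 1)]
    all_ids = sample_ids + npc_ids

    # ---- per-sample discrete structure -----------------------------------
    fgfr3_low = np.array([
        sg == "MMSET" and rng.random() < cfg.mmset_fgfr3_low_frac
        for sg in subgroups
    ])
    gep70_hr = np.array([
        rng.random() < cfg.gep70_hr_rates.get(sg, 0.0) for sg in subgroups
    ])

    alt_rows: list[dict] = []
    genes_per_sample: list[set[str]] = []
    for i, sid in enumerate(sample_ids):
        rows, hit = _draw_alterations(rng, sid, subgroups[i], stages_idx[i],
                                      cfg, fgfr3_low[i])
        alt_rows.extend(rows)
        genes_per_sample.append(hit)

    ras_mut = np.array([
        any(g in hit for g in ("KRAS", "NRAS", "BRAF")) for hit in genes_per_sample
    ])
    fgfr3_mut = np.array(["FGFR3" in hit for hit in genes_per_sample])
    adverse = np.array([
        any(g in hit for g in ADVERSE_GENES) for hit in genes_per_sample
    ])

    # ---- survival --------------------------------------------------------
    sp = cfg.survival_params
    hazard = sp.baseline_hazard * np.where(adverse, sp.hr_adverse, 1.0) \
        * np.where(gep70_hr, sp.hr_gep70, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / sp.censor_rate, size=n)
    os_months = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)

    npc_stage = rng.choice(3, size=cfg.n_npc, p=np.asarray(cfg.stage_proportions))
    npc_event_t = rng.exponential(1.0 / sp.baseline_hazard, size=cfg.n_npc)
    npc_censor_t = rng.exponential(1.0 / sp.censor_rate, size=cfg.n_npc)

    clinical = pd.DataFrame({
        "sample_id": all_ids,
        "stage": [STAGES[i] for i in stages_idx] + [STAGES[i] for i in npc_stage],
        "os_months": np.round(np.concatenate(
            [os_months, np.minimum(npc_event_t, npc_censor_t)]), 4),
        "os_event": np.concatenate(
            [os_event, (npc_event_t <= npc_censor_t).astype(int)]).astype(int),
    })

    # ---- expression ------------------------------------------------------
    probes = _probe_list(cfg.n_noise_probes)
    bg = cfg.spike_params.background
    spike = bg + cfg.spike_params.shift
    baseline = {p: bg for p in probes}
    for p, v in {
        "CCND2_1": 4.0, "CCND2_2": 4.0, "SULF2_1": 5.0, "NCAM1_1": 6.0,
        "S100A4_1": 7.0, "NES_1": 5.0, "DUSP6_1": 6.0, "DKK1_1": 6.0,
        "ETV5_1": 5.0, "COBLL1_1": 7.0, "MS4A1_1": 4.0, "FAF1_1": 7.0,
        "CDKN2C_1": 5.0, "CD19_1": 3.0, "VPREB3_1": 3.0,
    }.items():
        baseline[p] = v
    for p in DEFAULT_NFKB_PROBES:
        baseline[p] = 6.0
    for p in DEFAULT_GEP70_UP:
        baseline[p] = 5.5
    for p in DEFAULT_GEP70_DOWN:
        baseline[p] = 6.5
    for p in DEFAULT_PROLIF_PROBES:
        baseline[p] = 6.0
    noise_baselines = rng.uniform(3.0, 8.0, size=cfg.n_noise_probes)
    for i in range(cfg.n_noise_probes):
        baseline[f"NP{i + 1:04d}"] = float(noise_baselines[i])

    pix = {p: i for i, p in enumerate(probes)}
    mean = np.tile(
        np.array([baseline[p] for p in probes])[:, None], (1, len(all_ids))
    )
    nfkb = [pix[p] for p in DEFAULT_NFKB_PROBES]
    g70_up = [pix[p] for p in DEFAULT_GEP70_UP]
    g70_dn = [pix[p] for p in DEFAULT_GEP70_DOWN]
    prolif = [pix[p] for p in DEFAULT_PROLIF_PROBES]

    maf_uses_mafb = rng.random(n) < 0.30
    rras2_high = np.zeros(n, dtype=bool)
    ms4a1_high = np.zeros(n, dtype=bool)
    for i, sg in enumerate(subgroups):
        if sg == "D1-HRD":
            rras2_high[i] = rng.random() < (0.15 if ras_mut[i] else 0.45)
        if sg == "CCND1-11q13":
            ms4a1_high[i] = rng.random() < (0.443 if ras_mut[i] else 0.602)

    for i in range(n):
        sg = subgroups[i]
        col = mean[:, i]

        def add(probe_or_list, delta):
            if isinstance(probe_or_list, str):
                col[pix[probe_or_list]] += delta
            else:
                col[[pix[p] for p in probe_or_list]] += delta

        if sg == "D1-HRD":
            # moderate cyclin-D1 dysregulation, well below translocation spikes
            add(["CCND1_1", "CCND1_2"], 2.0)
            add(["ISL2_1", "TNFSF10_1"], 2.0)
            add("SULF2_1", 2.0)
            add("S100A4_1", -2.5)
            add("NES_1", -2.0)
            add("DKK1_1", 1.5)
            if rras2_high[i]:
                add("RRAS2_1", 3.0)
        elif sg == "D2":
            add(["CCND2_1", "CCND2_2"], 5.0)
            add("PTP4A3_1", 2.5)
            add("DUSP6_1", -2.0)
        elif sg == "CCND1-11q13":
            add(["CCND1_1", "CCND1_2"], 9.0)
            add("SLC8A1_1", 3.0)
            add("SULF2_1", -2.0)
            if ms4a1_high[i]:
                add("MS4A1_1", 3.0)
        elif sg == "CCND3-6p21":
            col[pix["CCND3_1"]] = spike
            add("USP49_1", 2.0)
        elif sg == "MMSET":
            col[pix["WHSC1_1"]] = spike
            add(["CCND2_1", "CCND2_2"], 5.0)
            add("DSG2_1", 2.5)
            if not fgfr3_low[i]:
                col[pix["FGFR3_1"]] = spike
        elif sg == "MAF":
            col[pix["MAFB_1" if maf_uses_mafb[i] else "MAF_1"]] = spike
            add(["CCND2_1", "CCND2_2"], 5.0)
            add(["NUAK1_1", "ITGB7_1"], 2.5)
            add("NCAM1_1", -2.5)
            add("DKK1_1", -1.5)
            col[nfkb] += 1.5

        if (ras_mut[i] or fgfr3_mut[i]) and sg != "MAF":
            col[nfkb] -= 1.0
        if ras_mut[i]:
            add("DUSP6_1", 1.5)
            add("SPRED2_1", 2.5)
            add("DKK1_1", 1.2)
            add("ETV5_1", 1.2)
            add("COBLL1_1", -1.5)
        if gep70_hr[i]:
            col[g70_up] += 2.0
            col[g70_dn] -= 2.0
        hit = genes_per_sample[i]
        if "CDKN2C" in hit:
            add("FAF1_1", -3.0)
        if "RB1" in hit:
            add("CDKN2C_1", 3.0)
        if "CDKN2C" in hit or "RB1" in hit:
            col[prolif] += 1.5

    npc_cols = slice(n, n + cfg.n_npc)
    mean[[pix["CD19_1"], pix["VPREB3_1"]], npc_cols] += 4.0
    mean[[pix["CCND1_1"], pix["CCND1_2"], pix["CCND2_1"], pix["CCND2_2"]],
         npc_cols] = 2.5

    values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    expr = pd.DataFrame(np.round(values, 6), index=probes, columns=all_ids)

    alterations = pd.DataFrame(
        alt_rows, columns=["sample_id", "gene", "alteration_type", "codon", "vaf"]
    )
    if not alterations.empty:
        alterations["vaf"] = alterations["vaf"].round(4)

    truth = pd.DataFrame({
        "sample_id": all_ids,
        "subgroup": list(subgroups) + ["NPC"] * cfg.n_npc,
        "stage": [STAGES[i] for i in stages_idx] + [STAGES[i] for i in npc_stage],
        "gep70_hr": np.concatenate([gep70_hr, np.zeros(cfg.n_npc, bool)]).astype(int),
        "adverse": np.concatenate([adverse, np.zeros(cfg.n_npc, bool)]).astype(int),
        "rasraf_mut": np.concatenate([ras_mut, np.zeros(cfg.n_npc, bool)]).astype(int),
        "fgfr3_mut": np.concatenate([fgfr3_mut, np.zeros(cfg.n_npc, bool)]).astype(int),
        "fgfr3_low": np.concatenate([fgfr3_low, np.zeros(cfg.n_npc, bool)]).astype(int),
    })
    arm = np.where(truth["adverse"].astype(bool) & truth["gep70_hr"].astype(bool),
                   "poor",
                   np.where(truth["adverse"].astype(bool) | truth["gep70_hr"].astype(bool),
                            "intermediate", "standard"))
    truth["risk_arm"] = arm

    return SyntheticCohort(expression=expr, alterations=alterations,
                           clinical=clinical, truth=truth, config=cfg)


FIXTURE_FILES = {
    "expression": "expression.tsv",
    "alterations": "alterations.tsv",
    "clinical": "clinical.tsv",
    "truth": "truth.tsv",
}


def write_fixtures(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort as tab-delimited fixtures; round-trips through
    :func:`read_cohort` within numeric formatting tolerance."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
        em.save_matrix(cohort.expression, paths["expression"])
        cohort.alterations.to_csv(paths["alterations"], sep="\t", index=False)
        cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
        cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write fixtures under {directory}: {exc}") from exc
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read a fixture directory written by :func:`write_fixtures`."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {k} fixture: {p}")
    expr = em.load_matrix(paths["expression"])
    str_cols = {"sample_id": str, "gene": str, "alteration_type": str, "codon": str}
    alterations = pd.read_csv(paths["alterations"], sep="\t", dtype=str_cols,
                              keep_default_na=False)
    alterations["vaf"] = pd.to_numeric(alterations["vaf"], errors="raise")
    clinical = pd.read_csv(paths["clinical"], sep="\t")
    truth = pd.read_csv(paths["truth"], sep="\t")
    return SyntheticCohort(expression=expr, alterations=alterations,
                           clinical=clinical, truth=truth)
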