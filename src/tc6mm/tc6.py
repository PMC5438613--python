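"""TC-6 molecular subgroup classification.

Multiple myeloma cases are grouped by their primary event: an IGH
translocation that drives a spike of the partner gene — t(11;14)/CCND1,
t(6;14)/CCND3, t(4;14)/MMSET (WHSC1, often with FGFR3), t(14;16)/t(14;20)
MAF/MAFB — or, in non-translocated cases, dysregulation of a D-group cyclin
(D1-HRD when CCND1 dominates, D2 when CCND2 does). Spikes are detected as
the upper component of a two-component Gaussian mixture per probe. Rule
labels seed a multiclass linear support-vector machine over a small
discriminating probe panel; the SVM weighs the whole expression composition
at once and includes a normal-plasma-cell (NPC) contamination class whose
calls are excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.svm import LinearSVC

__all__ = [
    "SUBGROUPS",
    "NPC_LABEL",
    "TC6Panel",
    "TC6Model",
    "DEFAULT_PANEL",
    "detect_spike_threshold",
    "rule_label",
    "train",
    "classify",
    "agreement",
]

SUBGROUPS = ("D1-HRD", "D2", "CCND1-11q13", "CCND3-6p21", "MMSET", "MAF")
NPC_LABEL = "NPC-contaminated"

#: spike precedence when a sample exceeds several spike thresholds; ordered
#: by decreasing biological rarity of co-occurrence
SPIKE_PRECEDENCE = ("MAF", "MMSET", "CCND3-6p21", "CCND1-11q13")


@dataclass(frozen=True)
class TC6Panel:
    """Probe roles for the TC-6 panel (probe identities are configuration)."""

    spike_probes: dict[str, tuple[str, ...]]
    ccnd1_probes: tuple[str, ...]
    ccnd2_probes: tuple[str, ...]
    secondary_probes: tuple[str, ...] = ()
    npc_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for sg, probes in self.spike_probes.items():
            if not probes:
                raise ValueError(f"empty spike probe list for {sg}")
        if not self.ccnd1_probes or not self.ccnd2_probes:
            raise ValueError("cyclin probe lists must be non-empty")
        if len(set(self.all_probes)) < 6:
            raise ValueError("panel needs >= 6 distinct probes")

    @property
    def all_probes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for probes in self.spike_probes.values():
            seen.update(dict.fromkeys(probes))
        for probes in (self.ccnd1_probes, self.ccnd2_probes,
                       self.secondary_probes, self.npc_probes):
            seen.update(dict.fromkeys(probes))
        return tuple(seen)


#: default 24-probe panel built from the genes that discriminate the
#: subgroups (the published probe identities are external configuration)
DEFAULT_PANEL = TC6Panel(
    spike_probes={
        "CCND1-11q13": ("CCND1_1", "CCND1_2"),
        "CCND3-6p21": ("CCND3_1",),
        "MMSET": ("WHSC1_1", "FGFR3_1"),
        "MAF": ("MAF_1", "MAFB_1"),
    },
    ccnd1_probes=("CCND1_1", "CCND1_2"),
    ccnd2_probes=("CCND2_1", "CCND2_2"),
    secondary_probes=(
        "SLC8A1_1", "SULF2_1", "NCAM1_1", "ITGB7_1", "NUAK1_1", "DSG2_1",
        "PTP4A3_1", "ISL2_1", "TNFSF10_1", "S100A4_1", "NES_1", "USP49_1",
        "DUSP6_1",
    ),
    npc_probes=("CD19_1", "VPREB3_1"),
)


def _require_probes(matrix: pd.DataFrame, probes) -> None:
    missing = [p for p in probes if p not in matrix.index]
    if missing:
        raise KeyError(f"panel probes absent from matrix: {missing}")


def detect_spike_threshold(values, seed: int = 0, min_separation: float = 1.0) -> float | None:
    """Threshold between background and spike expression for one probe.

    Fits a two-component 1-D Gaussian mixture (fixed seed) and returns the
    midpoint between the component means, or None when no spike population
    exists (component means closer than ``min_separation`` log2 units, or a
    constant vector).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError("need >= 20 samples to detect a spike population")
    if np.ptp(v) == 0:
        return None
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=10)
    gm.fit(v.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    if means[1] - means[0] < min_separation:
        return None
    return float(means.mean())


def _spike_thresholds(matrix: pd.DataFrame, panel: TC6Panel, seed: int) -> dict[str, float | None]:
    thresholds: dict[str, float | None] = {}
    for probes in panel.spike_probes.values():
        for p in probes:
            if p not in thresholds:
                thresholds[p] = detect_spike_threshold(matrix.loc[p], seed=seed)
    return thresholds


NPC_DISTANCE_RATIO = 0.7


def _npc_flags(matrix: pd.DataFrame, panel: TC6Panel, npc_centroid: pd.Series | None) -> np.ndarray:
    """Nearest-centroid contamination flag over panel probes.

    A sample is flagged when it lies markedly closer (Euclidean distance
    below ``NPC_DISTANCE_RATIO`` times the cohort-centroid distance) to the
    NPC centroid; the margin keeps heterogeneous tumor outliers from being
    discarded as contamination.
    """
    if npc_centroid is None:
        return np.zeros(matrix.shape[1], dtype=bool)
    probes = [p for p in panel.all_probes if p in npc_centroid.index]
    x = matrix.loc[probes].to_numpy().T
    cohort_centroid = x.mean(axis=0)
    npc = npc_centroid.loc[probes].to_numpy()
    d_npc = np.linalg.norm(x - npc, axis=1)
    d_cohort = np.linalg.norm(x - cohort_centroid, axis=1)
    return d_npc < NPC_DISTANCE_RATIO * d_cohort


def rule_label(
    matrix: pd.DataFrame,
    panel: TC6Panel = DEFAULT_PANEL,
    npc_centroid: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rule-based subgroup labels from spikes and cyclin dominance.

    Samples exceeding a spike threshold are assigned by the fixed precedence
    MAF > MMSET > CCND3-6p21 > CCND1-11q13; spike-free samples are D1-HRD
    when their mean CCND1 panel expression exceeds mean CCND2, else D2.
    Samples nearest an optional NPC centroid are flagged contaminated.
    Returns a frame (sample_id, subgroup, confidence, source="rule").
    """
    _require_probes(matrix, panel.all_probes)
    thresholds = _spike_thresholds(matrix, panel, seed)
    npc = _npc_flags(matrix, panel, npc_centroid)
    ccnd1 = matrix.loc[list(panel.ccnd1_probes)].mean(axis=0)
    ccnd2 = matrix.loc[list(panel.ccnd2_probes)].mean(axis=0)

    labels = []
    for j, sample in enumerate(matrix.columns):
        if npc[j]:
            labels.append(NPC_LABEL)
            continue
        assigned = None
        for sg in SPIKE_PRECEDENCE:
            for p in panel.spike_probes[sg]:
                thr = thresholds[p]
                if thr is not None and matrix.at[p, sample] > thr:
                    assigned = sg
                    break
            if assigned:
                break
        if assigned is None:
            assigned = "D1-HRD" if ccnd1[sample] > ccnd2[sample] else "D2"
        labels.append(assigned)
    return pd.DataFrame(
        {
            "sample_id": matrix.columns,
            "subgroup": labels,
            "confidence": 1.0,
            "source": "rule",
        }
    )


@dataclass
class TC6Model:
    """Trained TC-6 classifier: linear one-vs-rest SVM over panel probes."""

    panel: TC6Panel
    classes: tuple[str, ...]
    svm: LinearSVC
    feature_means: np.ndarray
    feature_sds: np.ndarray
    spike_thresholds: dict[str, float | None] = field(default_factory=dict)
    seed: int = 0

    @property
    def probes(self) -> tuple[str, ...]:
        return self.panel.all_probes


def train(
    matrix: pd.DataFrame,
    labels: pd.Series,
    panel: TC6Panel = DEFAULT_PANEL,
    seed: int = 0,
    c: float = 1.0,
) -> TC6Model:
    """Train the multiclass linear max-margin classifier on panel probes.

    ``labels`` maps sample_id -> subgroup and must cover all six subgroups
    plus the NPC contamination class with >= 2 samples each. Features are
    standardised with the training moments; regularisation C defaults to 1.
    Deterministic given data and seed.
    """
    _require_probes(matrix, panel.all_probes)
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    counts = labels.value_counts()
    required = set(SUBGROUPS) | {NPC_LABEL}
    thin = sorted(required - set(counts[counts >= 2].index))
    if thin:
        raise ValueError(f"classes absent or with < 2 training samples: {thin}")
    x = matrix.loc[list(panel.all_probes)].to_numpy().T
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    svm = LinearSVC(C=c, random_state=seed, max_iter=20000)
    svm.fit((x - mu) / sd, labels.to_numpy())
    return TC6Model(
        panel=panel,
        classes=tuple(svm.classes_),
        svm=svm,
        feature_means=mu,
        feature_sds=sd,
        spike_thresholds=_spike_thresholds(matrix, panel, seed),
        seed=seed,
    )


def classify(model: TC6Model, matrix: pd.DataFrame) -> pd.DataFrame:
    """One SubgroupCall row per sample from the trained model.

    Confidence is the softmax of the one-vs-rest decision margins for the
    winning class. NPC-predicted samples carry the contamination label and
    are excluded from downstream statistics by the analysis stages.
    """
    _require_probes(matrix, model.probes)
    x = matrix.loc[list(model.probes)].to_numpy().T
    z = (x - model.feature_means) / model.feature_sds
    margins = np.atleast_2d(model.svm.decision_function(z))
    pred = model.svm.predict(z)
    shifted = margins - margins.max(axis=1, keepdims=True)
    soft = np.exp(shifted)
    soft /= soft.sum(axis=1, keepdims=True)
    conf = soft.max(axis=1)
    return pd.DataFrame(
        {
            "sample_id": matrix.columns,
            "subgroup": pred,
            "confidence": conf,
            "source": "classifier",
        }
    )


def agreement(
    calls: pd.DataFrame,
    truth: pd.Series,
    mapping: dict[str, str] | None = None,
) -> float:
    """Fraction of non-NPC calls matching the truth labels.

    ``mapping`` optionally translates call labels into the truth vocabulary
    (e.g. subgroup -> iFISH translocation class). NPC-flagged samples leave
    the denominator entirely.
    """
    idx = calls.set_index("sample_id")["subgroup"]
    shared = idx.index.intersection(truth.index)
    if len(shared) == 0:
        raise ValueError("no shared sample IDs between calls and truth")
    got = idx.loc[shared]
    keep = got != NPC_LABEL
    got = got[keep]
    if mapping:
        got = got.map(lambda s: mapping.get(s, s))
    if got.empty:
        raise ValueError("all shared samples are NPC-flagged")
    return float((got == truth.loc[got.index]).mean())
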