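"""Gene-expression signature scores and dichotomous expression calls.

Signatures are configuration: named up/down probe lists with a combine rule
(plain mean, or mean(up) − mean(down)) and an optional threshold for binary
calls. The GEP70 risk score, the 11-gene NFκB activation index, and the
50-gene proliferation index all fit this shape; their published probe lists
are supplied by the user (synthetic cohorts plant their own).

Dichotomous expression calls (CD20/MS4A1 overexpression, FGFR3-low in
MMSET, FAF1-low / CDKN2C-high adverse signatures) reuse the two-component
mixture threshold from the subgroup classifier when no fixed threshold is
given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tc6 import detect_spike_threshold

__all__ = [
    "SignatureDef",
    "score",
    "binary_call",
    "mixture_call",
    "adverse_expression_signatures",
    "DEFAULT_NFKB_PROBES",
    "DEFAULT_GEP70_UP",
    "DEFAULT_GEP70_DOWN",
    "DEFAULT_PROLIF_PROBES",
]

# default probe lists matching the synthetic cohort generator; real-data
# users override these with the published lists
DEFAULT_NFKB_PROBES = (
    "BIRC3_1", "TNFAIP3_1", "NFKB2_1", "IL2RG_1", "NFKBIE_1", "RELB_1",
    "NFKBIA_1", "CD74_1", "PLEK_1", "MALT1_1", "WNT10A_1",
)
DEFAULT_GEP70_UP = ("CKS1B_1", "BIRC5_1", "ASPM_1", "AURKA_1", "KIF14_1")
DEFAULT_GEP70_DOWN = ("EVI5_1", "PNPLA4_1")
DEFAULT_PROLIF_PROBES = (
    "TOP2A_1", "MKI67_1", "CCNB1_1", "CCNB2_1", "BUB1_1",
    "CDC20_1", "PLK1_1", "TYMS_1", "RRM2_1", "PCNA_1",
)


@dataclass(frozen=True)
class SignatureDef:
    name: str
    up_probes: tuple[str, ...] = ()
    down_probes: tuple[str, ...] = ()
    combine: str = "mean_all"  # or "mean_up_minus_mean_down"
    threshold: float | None = None
    threshold_direction: str = "ge"  # "ge": >= threshold is positive; "le": <=

    def __post_init__(self) -> None:
        if not self.up_probes and not self.down_probes:
            raise ValueError(f"signature {self.name!r} has no probes")
        if self.combine not in ("mean_all", "mean_up_minus_mean_down"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if self.threshold_direction not in ("ge", "le"):
            raise ValueError("threshold_direction must be 'ge' or 'le'")


def _mean_rows(matrix: pd.DataFrame, probes) -> pd.Series:
    missing = [p for p in probes if p not in matrix.index]
    if missing:
        raise KeyError(f"signature probes absent from matrix: {missing}")
    return matrix.loc[list(probes)].mean(axis=0)


def score(matrix: pd.DataFrame, sig: SignatureDef) -> pd.Series:
    """Per-sample signature score under the signature's combine rule."""
    if sig.combine == "mean_all":
        return _mean_rows(matrix, sig.up_probes + sig.down_probes).rename(sig.name)
    up = _mean_rows(matrix, sig.up_probes)
    down = _mean_rows(matrix, sig.down_probes) if sig.down_probes else 0.0
    return (up - down).rename(sig.name)


def binary_call(scores: pd.Series, threshold: float, direction: str = "ge") -> pd.Series:
    """Deterministic dichotomous call; the boundary value is positive under
    'ge' (score >= threshold) and under 'le' (score <= threshold)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction == "ge":
        return scores >= threshold
    if direction == "le":
        return scores <= threshold
    raise ValueError("direction must be 'ge' or 'le'")


def mixture_call(
    values: pd.Series,
    tail: str = "high",
    seed: int = 0,
) -> tuple[pd.Series, float | None]:
    """Flag the high (or low) component of a bimodal expression distribution.

    The cut is the two-component mixture threshold; a unimodal distribution
    (no-spike sentinel) yields zero flags and a warning. Returns
    (flags, threshold).
    """
    thr = detect_spike_threshold(values, seed=seed)
    if thr is None:
        warnings.warn(f"{values.name}: no bimodal split detected, zero calls")
        return pd.Series(False, index=values.index, name=values.name), None
    flags = values > thr if tail == "high" else values < thr
    return flags.rename(values.name), thr


def adverse_expression_signatures(
    matrix: pd.DataFrame,
    faf1_probes,
    cdkn2c_probes,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint FAF1-low and CDKN2C-high adverse expression flags.

    FAF1-low tracks CDKN2C deletion and CDKN2C-high tracks RB1 alteration;
    either flag marks a proliferative, poor-outcome expression state. The
    thresholds are mixture-derived from the cohort itself. Samples may carry
    both flags; either-arm analyses count them once.
    """
    faf1 = _mean_rows(matrix, faf1_probes).rename("FAF1")
    cdkn2c = _mean_rows(matrix, cdkn2c_probes).rename("CDKN2C")
    faf1_low, _ = mixture_call(faf1, tail="low", seed=seed)
    cdkn2c_high, _ = mixture_call(cdkn2c, tail="high", seed=seed)
    return pd.DataFrame(
        {
            "FAF1_low": faf1_low,
            "CDKN2C_high": cdkn2c_high,
            "either": faf1_low | cdkn2c_high,
        }
    )
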