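"""Expression-matrix I/O, probe-to-gene aggregation, and reference-batch harmonization.

Matrices are plain :class:`pandas.DataFrame` objects with probe IDs in the
index and sample IDs in the columns, holding log2-scale values. Files are
tab-delimited with the probe ID in the first column and one header row of
sample IDs (a minimal GCT-like layout).

Harmonization follows the M-ComBat idea: instead of shifting every batch
toward the grand mean as ordinary ComBat does, the target batch's per-probe
location and scale are mapped onto those of a fixed reference batch, so the
reference cohort's coordinate system is preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeSet",
    "load_matrix",
    "save_matrix",
    "gene_level",
    "mcombat_adjust",
]


@dataclass(frozen=True)
class ProbeSet:
    """A gene and the probes averaged to represent it."""

    gene: str
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"probe set for gene {self.gene!r} is empty")
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))


class ExpressionParseError(ValueError):
    """Raised when an expression file violates the documented format."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an expression matrix."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"duplicate probe IDs: {dups}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ExpressionParseError(f"duplicate sample IDs: {dups}")
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)].tolist()[:5]
        raise ExpressionParseError(f"missing values in probes {bad}")
    return matrix


def load_matrix(path, log2: bool = False) -> pd.DataFrame:
    """Read a tab-delimited probe-by-sample expression matrix.

    Parameters
    ----------
    path
        Tab-delimited file: first column probe IDs, header row sample IDs.
    log2
        If True, values are linear-scale and are transformed x -> log2(x+1)
        on load. Default assumes values already on the log2 scale.
    """
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ExpressionParseError(f"cannot parse {path}: {exc}") from exc
    non_numeric = matrix.columns[
        [not np.issubdtype(dt, np.number) for dt in matrix.dtypes]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad_rows = matrix.index[
                pd.to_numeric(matrix[col], errors="coerce").isna()
            ].tolist()[:5]
            raise ExpressionParseError(
                f"non-numeric cells in {path}, column {col!r}, probes {bad_rows}"
            )
    matrix.index = matrix.index.astype(str)
    matrix = matrix.astype(float)
    validate_matrix(matrix)
    if log2:
        if (matrix.to_numpy() < 0).any():
            raise ExpressionParseError("negative values under --log2 transform")
        matrix = np.log2(matrix + 1.0)
    return matrix


def save_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in the same tab-delimited layout ``load_matrix`` reads."""
    validate_matrix(matrix)
    out = matrix.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def gene_level(matrix: pd.DataFrame, probesets: Sequence[ProbeSet]) -> pd.DataFrame:
    """Collapse probes to genes by the arithmetic mean of each gene's probes.

    Every configured probe must be present; a missing probe is an error
    naming both the gene and the probe.
    """
    rows = {}
    for ps in probesets:
        missing = [p for p in ps.probe_ids if p not in matrix.index]
        if missing:
            raise KeyError(
                f"gene {ps.gene!r}: probes {missing} absent from matrix"
            )
        rows[ps.gene] = matrix.loc[list(ps.probe_ids)].mean(axis=0)
    return pd.DataFrame(rows).T


def _batch_moments(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    return mean, sd


def mcombat_adjust(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    eb: bool = False,
    on_zero_variance: str = "error",
) -> pd.DataFrame:
    """Map the target batch onto the reference batch's per-probe moments.

    Default (non-EB) mode rescales each shared probe:

        adjusted = (x - mean_target) / sd_target * sd_ref + mean_ref

    so the adjusted target batch has exactly the reference's per-probe mean
    and standard deviation. With ``eb=True`` the per-probe target moments are
    first shrunk toward their cross-probe averages by method-of-moments
    empirical-Bayes weights before the mapping, which stabilises probes whose
    batch parameters are poorly estimated at small sample size.

    Parameters
    ----------
    target, reference
        Probe-by-sample matrices sharing a probe set; each needs >= 2 samples.
    on_zero_variance
        "error" (default) raises on a zero-variance target probe; "passthrough"
        leaves such probes shifted to the reference mean with a warning.
    """
    shared = target.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("target and reference share no probes")
    if target.shape[1] < 2 or reference.shape[1] < 2:
        raise ValueError("each batch needs >= 2 samples for variance estimates")
    tgt = target.loc[shared]
    ref = reference.loc[shared]

    t_mean, t_sd = _batch_moments(tgt)
    r_mean, r_sd = _batch_moments(ref)

    if eb:
        # Method-of-moments shrinkage of per-probe batch parameters toward
        # their cross-probe average, in the spirit of ComBat's EB step.
        g = t_mean - t_mean.mean()
        tau2 = max(g.var(ddof=1) - (t_sd**2).mean() / tgt.shape[1], 1e-12)
        w = tau2 / (tau2 + (t_sd**2) / tgt.shape[1])
        t_mean = t_mean.mean() + w * g
        logv = np.log(np.maximum(t_sd**2, 1e-12))
        lv_bar = logv.mean()
        lv_var = logv.var(ddof=1)
        w_v = lv_var / (lv_var + 2.0 / max(tgt.shape[1] - 1, 1))
        t_sd = np.sqrt(np.exp(lv_bar + w_v * (logv - lv_bar)))

    zero = t_sd <= 0
    if zero.any():
        probes = t_sd.index[zero].tolist()
        if on_zero_variance == "error":
            raise ValueError(f"zero target variance on probes {probes}")
        warnings.warn(f"zero-variance probes passed through: {probes}")
        t_sd = t_sd.mask(zero, 1.0)
        r_sd = r_sd.mask(zero, 0.0)

    centered = tgt.sub(t_mean, axis=0).div(t_sd, axis=0)
    return centered.mul(r_sd, axis=0).add(r_mean, axis=0)
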