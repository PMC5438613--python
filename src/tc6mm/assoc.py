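"""Variant filtering and contingency statistics for targeted-panel calls.

The alteration table is a tidy DataFrame with one row per call:
``sample_id, gene, alteration_type, codon, vaf``. RAS-pathway genes are
restricted to known activating hotspots (KRAS/NRAS G12, G13, Q61 missense;
BRAF V600E missense) and all calls must clear the 5% variant-allele-frequency
floor of the panel. Association tests are the two-sided Fisher exact test,
the Cochran-Armitage trend test over ordered disease stages, a two-sample
rank test, and a stage-adjusted logistic model with likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ALTERATION_TYPES",
    "RAS_RAF_GENES",
    "ContingencyResult",
    "TrendResult",
    "filter_variants",
    "resolve_ras_raf",
    "fisher_2x2",
    "cochran_armitage",
    "rank_test",
    "subgroup_enrichment",
    "stage_adjusted_logistic",
]

ALTERATION_TYPES = ("missense", "frameshift", "nonsense", "splice", "deletion")

#: gene -> allowed activating codons; also the tie-break precedence order
RAS_RAF_GENES = {"KRAS": ("G12", "G13", "Q61"), "NRAS": ("G12", "G13", "Q61"), "BRAF": ("V600E",)}

VAF_FLOOR = 0.05


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 table, odds ratio, and two-sided exact p."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


@dataclass(frozen=True)
class TrendResult:
    """Cochran-Armitage trend test over ordered groups."""

    counts: tuple[int, ...]
    totals: tuple[int, ...]
    scores: tuple[float, ...]
    z: float
    p_two_sided: float


def _check_alteration_table(table: pd.DataFrame) -> None:
    required = {"sample_id", "gene", "alteration_type", "codon", "vaf"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"alteration table missing columns {sorted(missing)}")


def filter_variants(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the panel's retention rules.

    Drops calls with VAF below 5% (boundary inclusive: 0.05 is kept). For
    KRAS/NRAS only missense calls at G12/G13/Q61 survive; for BRAF only
    missense V600E. All other genes keep every short-variant class plus
    homozygous deletions. Idempotent. A RAS-RAF call whose codon field is
    empty or not a recognised hotspot string is an error, since hotspot
    membership cannot be decided for it.
    """
    _check_alteration_table(raw)
    if raw.empty:
        return raw.copy()
    tab = raw[raw["vaf"].astype(float) >= VAF_FLOOR].copy()
    keep = np.ones(len(tab), dtype=bool)
    for i, row in enumerate(tab.itertuples(index=False)):
        if row.gene in RAS_RAF_GENES:
            codon = "" if pd.isna(row.codon) else str(row.codon)
            if codon == "" or not any(ch.isdigit() for ch in codon):
                raise ValueError(
                    f"malformed codon {codon!r} for {row.gene} in sample {row.sample_id}"
                )
            keep[i] = (
                row.alteration_type == "missense"
                and codon in RAS_RAF_GENES[row.gene]
            )
    return tab[keep].reset_index(drop=True)


def resolve_ras_raf(filtered: pd.DataFrame) -> pd.DataFrame:
    """Collapse co-occurring RAS-RAF calls to one per sample.

    Samples with multiple RAS-pathway hotspot calls keep only the call with
    the highest VAF; exact VAF ties are broken by the fixed gene order
    KRAS > NRAS > BRAF. Non-RAS-RAF rows pass through untouched.
    """
    _check_alteration_table(filtered)
    is_ras = filtered["gene"].isin(RAS_RAF_GENES)
    ras = filtered[is_ras].copy()
    if ras.empty:
        return filtered.copy()
    order = {g: i for i, g in enumerate(RAS_RAF_GENES)}  # KRAS < NRAS < BRAF
    ras["_rank"] = ras["gene"].map(order)
    ras = ras.sort_values(
        ["sample_id", "vaf", "_rank"], ascending=[True, False, True], kind="mergesort"
    )
    ras = ras.drop_duplicates("sample_id", keep="first").drop(columns="_rank")
    out = pd.concat([filtered[~is_ras], ras], ignore_index=True)
    return out.sort_values(["sample_id", "gene"], kind="mergesort").reset_index(drop=True)


def fisher_2x2(table, method: str = "mass") -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table of non-negative counts.

    ``method="mass"`` (default) sums hypergeometric probabilities at most the
    observed table's probability — the rule most statistical software uses.
    ``method="doubling"`` doubles the smaller one-sided tail (capped at 1).
    The odds ratio is the sample ratio ad/bc, infinite when bc = 0.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must be 2x2 non-negative integers")
    arr = arr.astype(int)
    (a, b), (c, d) = arr
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero margin in 2x2 table")
    if method == "mass":
        _, p = stats.fisher_exact(arr, alternative="two-sided")
    elif method == "doubling":
        n, k, m = a + b + c + d, a + b, a + c
        lo = stats.hypergeom.cdf(a, n, k, m)
        hi = stats.hypergeom.sf(a - 1, n, k, m)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise ValueError(f"unknown method {method!r}")
    oratio = np.inf if b * c == 0 else (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), float(oratio), float(p))


def cochran_armitage(
    counts: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> TrendResult:
    """Asymptotic Cochran-Armitage test for trend in proportions.

    Z = sum s_i (k_i - n_i pbar) / sqrt( pbar (1-pbar) *
        [sum n_i s_i^2 - (sum n_i s_i)^2 / N] ),  p = 2 (1 - Phi(|Z|)).

    Scores default to equally spaced 0, 1, 2, ... over the ordered groups.
    Degenerate inputs (no events, or all events) give Z = 0, p = 1 with a
    warning.
    """
    k = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if k.shape != n.shape or k.ndim != 1 or len(k) < 2:
        raise ValueError("need >= 2 ordered groups with matching counts/totals")
    if (n <= 0).any() or (k < 0).any() or (k > n).any():
        raise ValueError("counts must satisfy 0 <= k_i <= n_i, n_i > 0")
    s = np.arange(len(k), dtype=float) if scores is None else np.asarray(scores, float)
    big_n = n.sum()
    pbar = k.sum() / big_n
    if pbar in (0.0, 1.0):
        warnings.warn("all-zero or all-full counts: trend undefined, Z=0")
        return TrendResult(tuple(int(x) for x in k), tuple(int(x) for x in n),
                           tuple(s), 0.0, 1.0)
    num = float(np.sum(s * (k - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / big_n)
    if var <= 0:
        raise ValueError("degenerate scores: zero trend variance")
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(tuple(int(x) for x in k), tuple(int(x) for x in n),
                       tuple(s), float(z), float(min(p, 1.0)))


def rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum p-value.

    Exact enumeration (no ties, both groups <= 10) via the exact
    Mann-Whitney distribution; otherwise the normal approximation with
    midrank tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs >= 1 value")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size <= 10 and b.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def subgroup_enrichment(
    alterations: pd.DataFrame,
    calls: pd.DataFrame,
    gene: str,
    partition: tuple[Iterable[str], Iterable[str]],
    codon: str | None = None,
) -> ContingencyResult:
    """Fisher test of alteration presence across a two-set subgroup partition.

    ``calls`` is a subgroup-call table (``sample_id, subgroup, ...``);
    NPC-contaminated samples are excluded before counting. Presence is at
    the sample level: any qualifying call for ``gene`` (optionally restricted
    to one codon label) marks the sample altered.
    """
    set_a, set_b = (set(p) for p in partition)
    if set_a & set_b:
        raise ValueError("partition sides overlap")
    usable = calls[calls["subgroup"] != "NPC-contaminated"]
    in_a = usable.loc[usable["subgroup"].isin(set_a), "sample_id"]
    in_b = usable.loc[usable["subgroup"].isin(set_b), "sample_id"]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValueError("empty partition side")
    hits = alterations[alterations["gene"] == gene]
    if codon is not None:
        hits = hits[hits["codon"] == codon]
    mutated = set(hits["sample_id"])
    a = sum(s in mutated for s in in_a)
    c = sum(s in mutated for s in in_b)
    return fisher_2x2([[a, len(in_a) - a], [c, len(in_b) - c]])


@dataclass
class LogisticTermResult:
    term: str
    coefficients: dict[str, float] = field(default_factory=dict)
    lr_statistic: float = np.nan
    df: int = 0
    p_value: float = np.nan
    unstable: bool = False


def _fit_logit(y: np.ndarray, x: pd.DataFrame):
    model = sm.GLM(y, sm.add_constant(x, has_constant="add"),
                   family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def stage_adjusted_logistic(
    outcome: Sequence[int],
    subgroup: Sequence[str],
    stage: Sequence[str],
) -> list[LogisticTermResult]:
    """Logistic model of a binary outcome on subgroup + stage factors.

    Fits by IRLS and reports, for each factor, the likelihood-ratio test
    against the model without that factor. Coefficients larger than 10 in
    absolute value (log-odds) are flagged as unstable, the usual footprint
    of (quasi-)complete separation.
    """
    y = np.asarray(outcome, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome needs >= 1 event and >= 1 non-event")
    frame = pd.DataFrame({"subgroup": list(subgroup), "stage": list(stage)})
    design = {
        term: pd.get_dummies(frame[term], prefix=term, drop_first=True, dtype=float)
        for term in ("subgroup", "stage")
    }
    full_x = pd.concat(design.values(), axis=1)
    full = _fit_logit(y, full_x)
    results = []
    for term, block in design.items():
        reduced_x = full_x.drop(columns=block.columns)
        reduced = _fit_logit(y, reduced_x)
        lr = 2.0 * (full.llf - reduced.llf)
        df = block.shape[1]
        coefs = {name: float(full.params[name]) for name in block.columns}
        results.append(
            LogisticTermResult(
                term=term,
                coefficients=coefs,
                lr_statistic=float(max(lr, 0.0)),
                df=df,
                p_value=float(stats.chi2.sf(max(lr, 0.0), df)),
                unstable=any(abs(v) > 10 for v in coefs.values()),
            )
        )
    return results
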