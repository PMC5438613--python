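"""Survival analysis: Kaplan-Meier, log-rank, conditional-inference trees,
and the GEP70 x adverse-alteration three-arm stratification.

The adverse-alteration discovery step is a conditional-inference-style
recursive partitioning of overall survival on binary alteration indicators:
at each node every candidate gene is tested by a two-group log-rank test,
p-values are Bonferroni-adjusted across the candidates actually tested at
that node, and the node splits on the smallest adjusted p only when it
clears ``alpha``. Leaves carry Kaplan-Meier curves. Analyses mirroring the
non-relapse clinical setting take an explicit subset flag upstream; nothing
is subset implicitly here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .assoc import ContingencyResult, fisher_2x2

__all__ = [
    "KMCurve",
    "CITreeNode",
    "km",
    "os_at",
    "logrank",
    "ci_tree",
    "three_arm",
    "ThreeArmResult",
    "mutual_exclusivity_check",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with at-risk counts and Greenwood variance."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    n: int


def _check_times(times: np.ndarray) -> None:
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("survival times must be finite and >= 0")


def km(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) is the standard right-continuous step function: a death at exactly
    t is included in S(t), i.e. S(t) = P(T > t).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need >= 1 subject")
    _check_times(t)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    ev_times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n_risk = ev["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    # Greenwood: var(S) = S^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = d / (n_risk * (n_risk - d))
        increments[~np.isfinite(increments)] = 0.0
    gw = surv**2 * np.cumsum(increments)
    return KMCurve(
        times=ev_times,
        survival=surv,
        at_risk=n_risk,
        n_events=d.astype(int),
        greenwood_var=gw,
        n=int(t.size),
    )


def os_at(curve: KMCurve, t: float) -> float:
    """Step-function survival probability at time t (deaths at t included)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank(times, events, group) -> tuple[float, float]:
    """k-group log-rank test: observed-minus-expected with hypergeometric
    variance, chi-square on k - 1 degrees of freedom.

    Returns (statistic, p). Vectorised over distinct event times so it is
    cheap enough to sit inside the tree search.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    _check_times(t)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups (single stratum)")
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return 0.0, 1.0
    # at-risk counts per group at each event time; deaths per group
    n_risk = np.empty((k, ev_times.size))
    deaths = np.empty((k, ev_times.size))
    for j, lab in enumerate(labels):
        tj = np.sort(t[g == lab])
        n_risk[j] = tj.size - np.searchsorted(tj, ev_times, side="left")
        tj_ev = np.sort(t[(g == lab) & (e == 1)])
        deaths[j] = np.searchsorted(tj_ev, ev_times, side="right") - np.searchsorted(
            tj_ev, ev_times, side="left"
        )
    n_tot = n_risk.sum(axis=0)
    d_tot = deaths.sum(axis=0)
    valid = n_tot > 0
    n_risk, deaths = n_risk[:, valid], deaths[:, valid]
    n_tot, d_tot = n_tot[valid], d_tot[valid]
    expected = n_risk * (d_tot / n_tot)
    o_minus_e = (deaths - expected).sum(axis=1)[: k - 1]
    # covariance of the first k-1 group death counts, summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    frac = n_risk / n_tot
    cov = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            diag = frac[a] * (1.0 - frac[a]) if a == b else -frac[a] * frac[b]
            cov[a, b] = np.sum(mult * diag)
    try:
        stat = float(o_minus_e @ np.linalg.solve(cov, o_minus_e))
    except np.linalg.LinAlgError:
        stat = float(o_minus_e @ np.linalg.pinv(cov) @ o_minus_e)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return stat, p


@dataclass
class CITreeNode:
    n: int
    curve: KMCurve
    feature: str | None = None
    p_adjusted: float = np.nan
    n_candidates_tested: int = 0
    left: "CITreeNode | None" = None  # feature absent
    right: "CITreeNode | None" = None  # feature present
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_text(self) -> str:
        pad = "  " * self.depth
        if self.is_leaf:
            return f"{pad}leaf: n={self.n}\n"
        out = (
            f"{pad}split on {self.feature} "
            f"(Bonferroni p={self.p_adjusted:.3g}, n={self.n})\n"
        )
        return out + self.left.to_text() + self.right.to_text()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "n": self.n}
        return {
            "leaf": False,
            "feature": self.feature,
            "p_adjusted": self.p_adjusted,
            "n": self.n,
            "absent": self.left.to_dict(),
            "present": self.right.to_dict(),
        }


def ci_tree(
    times,
    events,
    features: pd.DataFrame,
    alpha: float = 0.05,
    min_node: int = 20,
    n_permutations: int = 0,
    seed: int = 0,
    _depth: int = 0,
) -> CITreeNode:
    """Conditional-inference-style survival tree over binary alterations.

    At each node, every candidate column of ``features`` with both classes
    represented (and both resulting children >= ``min_node``) is tested by a
    two-group log-rank test; p-values are Bonferroni-multiplied by the number
    of candidates tested at the node, and the node splits on the minimum
    adjusted p when it is below ``alpha``. ``n_permutations > 0`` replaces
    the asymptotic per-candidate p by a label-permutation p with a fixed
    seed. Deterministic given inputs (and seed).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if features.shape[0] != t.size:
        raise ValueError("feature rows must match subjects")
    node = CITreeNode(n=int(t.size), curve=km(t, e), depth=_depth)
    if t.size < 2 * min_node:  # no admissible split exists
        return node
    best = (np.inf, None)
    tested = 0
    rng = np.random.default_rng(seed + 7919 * _depth)
    for name in features.columns:
        f = features[name].to_numpy().astype(bool)
        n_pos = int(f.sum())
        if min(n_pos, t.size - n_pos) < min_node:
            continue
        tested += 1
        stat, p = logrank(t, e, f.astype(int))
        if n_permutations > 0:
            perm_stats = np.empty(n_permutations)
            for b in range(n_permutations):
                perm = rng.permutation(f)
                perm_stats[b], _ = logrank(t, e, perm.astype(int))
            p = (1.0 + np.sum(perm_stats >= stat)) / (n_permutations + 1.0)
        if p < best[0]:
            best = (p, name)
    node.n_candidates_tested = tested
    if tested == 0:
        return node
    p_adj = min(1.0, best[0] * tested)
    if p_adj < alpha and best[1] is not None:
        node.feature = best[1]
        node.p_adjusted = p_adj
        f = features[best[1]].to_numpy().astype(bool)
        node.left = ci_tree(
            t[~f], e[~f], features.loc[~f], alpha, min_node,
            n_permutations, seed, _depth + 1,
        )
        node.right = ci_tree(
            t[f], e[f], features.loc[f], alpha, min_node,
            n_permutations, seed, _depth + 1,
        )
    return node


@dataclass
class ThreeArmResult:
    arms: pd.Series  # per-sample arm label
    sizes: dict[str, int]
    curves: dict[str, KMCurve]
    os_18: dict[str, float]
    logrank_stat: float
    logrank_p: float


ARM_ORDER = ("poor", "intermediate", "standard")


def three_arm(times, events, adverse_flag, gep70_hr_flag,
              sample_ids=None, horizon: float = 18.0) -> ThreeArmResult:
    """Stratify by GEP70 risk x adverse-alteration status.

    poor = both flags, intermediate = exactly one, standard = neither.
    Returns per-arm Kaplan-Meier curves, OS at ``horizon`` months, and the
    k-group log-rank p across the arms present. A cohort collapsing to a
    single stratum raises, since no between-arm comparison exists.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    adv = np.asarray(adverse_flag)
    hr = np.asarray(gep70_hr_flag)
    for name, flags in (("adverse_flag", adv), ("gep70_hr_flag", hr)):
        if pd.isna(flags).any():
            raise ValueError(f"{name} contains missing values")
    adv = adv.astype(bool)
    hr = hr.astype(bool)
    arm = np.where(adv & hr, "poor", np.where(adv | hr, "intermediate", "standard"))
    index = sample_ids if sample_ids is not None else pd.RangeIndex(t.size)
    arms = pd.Series(arm, index=index, name="risk_arm")
    present = [a for a in ARM_ORDER if (arm == a).any()]
    if len(present) < 2:
        raise ValueError("single stratum: all samples fall in one arm")
    curves = {a: km(t[arm == a], e[arm == a]) for a in present}
    stat, p = logrank(t, e, arm)
    return ThreeArmResult(
        arms=arms,
        sizes={a: int((arm == a).sum()) for a in present},
        curves=curves,
        os_18={a: os_at(curves[a], horizon) for a in present},
        logrank_stat=stat,
        logrank_p=p,
    )


def mutual_exclusivity_check(
    alterations: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    sample_ids,
) -> tuple[int, ContingencyResult | None]:
    """Co-occurrence count and Fisher test for two genes' alteration sets.

    ``sample_ids`` defines the cohort universe. Returns the number of samples
    altered in both genes and the Fisher result on the joint 2x2 (None when a
    zero margin makes the test undefined, e.g. a gene absent from the table —
    reported with a warning).
    """
    universe = list(sample_ids)
    set_a = set(alterations.loc[alterations["gene"] == gene_a, "sample_id"])
    set_b = set(alterations.loc[alterations["gene"] == gene_b, "sample_id"])
    both = sum(1 for s in universe if s in set_a and s in set_b)
    a_only = sum(1 for s in universe if s in set_a and s not in set_b)
    b_only = sum(1 for s in universe if s not in set_a and s in set_b)
    neither = len(universe) - both - a_only - b_only
    try:
        result = fisher_2x2([[both, a_only], [b_only, neither]])
    except ValueError:
        warnings.warn(
            f"{gene_a}/{gene_b}: zero margin (gene absent?), Fisher undefined"
        )
        result = None
    return both, result
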