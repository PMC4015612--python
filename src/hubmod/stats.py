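"""Differential-correlation statistics and the permutation test.

For each network module the hub-partner expression correlation is
computed separately in every biological condition.  The null hypothesis
is that the *average* hub-partner correlation is the same in all
conditions.  The test statistic is the absolute difference of the two
condition means when there are exactly two conditions, and a one-way
ANOVA F on the correlation values (grouped by condition) when there are
more.  Significance is assessed by permuting the sample-to-condition
assignment — one global permutation applied to all genes at once, so the
gene-gene dependence structure is preserved under the null — and
recomputing the full profile and statistic.

Sampled mode reports the add-one permutation p,
``(1 + #{null >= observed}) / (B + 1)``, which is never zero (a
requirement for downstream Fisher combination); exhaustive mode
enumerates every distinct assignment of the condition labels (the
identity included) and reports the exact tail fraction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import (ConditionLabels, ExpressionMatrix, HubTestResult,
                         Network, NetworkModule, ValidationError)
from .network import DEFAULT_MIN_PARTNERS, identify_hubs

logger = logging.getLogger(__name__)

DEFAULT_EXHAUSTIVE_CAP = 10_000


class DegenerateModuleError(ValidationError):
    """A module lost too many partners to undefined correlations."""


@dataclass
class PermutationPlan:
    """How to build the permutation null.

    ``seed`` is mandatory: every run is reproducible from its plan.
    ``mode`` is "sampled" (B random label shuffles, add-one p) or
    "exhaustive" (all distinct assignments, allowed only when their
    number does not exceed ``exhaustive_cap``).
    """

    seed: int
    n_permutations: int = 1000
    mode: str = "sampled"
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP

    def __post_init__(self) -> None:
        if self.mode not in ("sampled", "exhaustive"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.mode == "sampled" and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1 in sampled mode")


@dataclass
class CorrelationProfile:
    """Per-partner, per-condition hub correlation matrix for one module.

    ``corr`` has one row per surviving partner and one column per
    condition (in the order of ``conditions``); every retained entry is
    finite and in [-1, 1].  Partners whose correlation is undefined in
    any condition are dropped module-wide before the statistic is formed,
    so the statistic compares like with like across permutations.
    """

    hub: str
    partner_ids: tuple
    conditions: tuple
    corr: np.ndarray
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def pair_correlation(x, y, method: str = "pearson") -> float:
    """Correlation of two vectors over pairwise-complete entries.

    Returns NaN (undefined) when fewer than three complete pairs remain
    or either vector has zero variance on the complete pairs.
    """
    _check_method(method)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return float("nan")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    if method == "spearman":
        xv, yv = rankdata(xv), rankdata(yv)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            return float("nan")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    den = math.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def _check_method(method: str) -> None:
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")


def _corr_groups(X: np.ndarray, group_cols: list[np.ndarray],
                 method: str) -> np.ndarray:
    """Hub (row 0) vs partners (rows 1..k) correlation per column group.

    Returns a (k, C) matrix with NaN where the correlation is undefined
    (group smaller than 3, or zero variance within the group).
    """
    k = X.shape[0] - 1
    out = np.empty((k, len(group_cols)), dtype=float)
    if np.isnan(X).any():
        for ci, cols in enumerate(group_cols):
            hub = X[0, cols]
            for j in range(k):
                out[j, ci] = pair_correlation(hub, X[j + 1, cols], method)
        return out
    for ci, cols in enumerate(group_cols):
        S = X[:, cols]
        if S.shape[1] < 3:
            out[:, ci] = np.nan
            continue
        constant = np.ptp(S, axis=1) == 0
        if method == "spearman":
            S = rankdata(S, axis=1)
        S = S - S.mean(axis=1, keepdims=True)
        h = S[0]
        P = S[1:]
        hss = float(h @ h)
        pss = np.einsum("ij,ij->i", P, P)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (P @ h) / np.sqrt(pss * hss)
        r = np.clip(r, -1.0, 1.0)
        undef = constant[1:] | (pss == 0)
        if constant[0] or hss == 0:
            undef[:] = True
        r[undef] = np.nan
        out[:, ci] = r
    return out


# ---------------------------------------------------------------------------
# Module profile
# ---------------------------------------------------------------------------

def _module_matrix(expr: ExpressionMatrix, labels: ConditionLabels,
                   module: NetworkModule):
    """Module expression submatrix over labelled samples, plus the base
    condition-index vector and group column indices (in expression column
    order)."""
    used = [s for s in expr.sample_ids if s in labels.assignment]
    if not used:
        raise ValidationError("no labelled sample present in expression data")
    cond_index = {c: i for i, c in enumerate(labels.conditions)}
    base = np.array([cond_index[labels.assignment[s]] for s in used],
                    dtype=np.int64)
    missing = [g for g in (module.hub, *module.partners)
               if g not in expr.data.index]
    if missing:
        raise ValidationError(
            f"module members absent from expression data: {missing[:5]}")
    X = expr.data.loc[[module.hub, *module.partners], used].to_numpy()
    return X, base


def _group_cols(base: np.ndarray, n_conditions: int) -> list[np.ndarray]:
    return [np.flatnonzero(base == c) for c in range(n_conditions)]


def module_profile(expr: ExpressionMatrix, labels: ConditionLabels,
                   module: NetworkModule, method: str = "pearson",
                   min_partners: int = 1) -> CorrelationProfile:
    """Per-condition hub-partner correlations for one module.

    Partners whose correlation is undefined in *any* condition are
    dropped (the drop is logged); the module is rejected when fewer than
    ``min_partners`` partners survive.
    """
    _check_method(method)
    X, base = _module_matrix(expr, labels, module)
    cols = _group_cols(base, len(labels.conditions))
    corr = _corr_groups(X, cols, method)
    kept = np.isfinite(corr).all(axis=1)
    n_dropped = int((~kept).sum())
    if n_dropped:
        dropped_ids = [p for p, k in zip(module.partners, kept) if not k]
        logger.info("module %s: dropped %d partners with undefined "
                    "correlations: %s", module.hub, n_dropped, dropped_ids[:5])
    if kept.sum() == 0:
        raise DegenerateModuleError(
            f"module {module.hub}: all partners undefined; module excluded")
    if kept.sum() < min_partners:
        raise DegenerateModuleError(
            f"module {module.hub}: only {int(kept.sum())} partners survive "
            f"(< {min_partners})")
    return CorrelationProfile(
        hub=module.hub,
        partner_ids=tuple(p for p, k in zip(module.partners, kept) if k),
        conditions=tuple(labels.conditions),
        corr=corr[kept],
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Test statistics
# ---------------------------------------------------------------------------

def two_condition_statistic(profile: CorrelationProfile) -> float:
    """Absolute difference of the two condition mean correlations."""
    if len(profile.conditions) != 2:
        raise ValueError(
            "two_condition_statistic requires exactly 2 conditions; "
            "use f_statistic for more")
    return _mean_difference(profile.corr)


def f_statistic(profile: CorrelationProfile) -> float:
    """One-way ANOVA F on correlation values grouped by condition.

    The correlations are treated as independent observations within each
    condition group (partner pairing across conditions is ignored).
    Returns 0 when both mean squares vanish and +inf when only the
    within-group mean square does.
    """
    if len(profile.conditions) < 2:
        raise ValueError("f_statistic requires >= 2 conditions")
    if profile.corr.shape[0] < 2:
        raise ValueError("f_statistic requires >= 2 defined partners")
    return _anova_f(profile.corr)


def _mean_difference(corr: np.ndarray) -> float:
    means = np.nanmean(corr, axis=0)
    return float(abs(means[0] - means[1]))


def _anova_f(corr: np.ndarray) -> float:
    groups = [col[np.isfinite(col)] for col in corr.T]
    sizes = np.array([len(g) for g in groups])
    if (sizes == 0).any():
        return float("nan")
    n_total = int(sizes.sum())
    n_groups = len(groups)
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between = n_groups - 1
    df_within = n_total - n_groups
    if df_within <= 0:
        return float("nan")
    msb = ssb / df_between
    msw = ssw / df_within
    if msw == 0:
        return 0.0 if msb == 0 else float("inf")
    return msb / msw


def _stat_from_corr(corr: np.ndarray, kind: str) -> float:
    """Statistic on an already-filtered (finite) correlation matrix;
    NaN when undefined for this permutation."""
    kept = np.isfinite(corr).all(axis=1)
    sub = corr[kept]
    if kind == "mean_difference":
        if sub.shape[0] == 0:
            return float("nan")
        return _mean_difference(sub)
    if sub.shape[0] < 2:
        return float("nan")
    return _anova_f(sub)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _count_assignments(counts) -> int:
    total = math.factorial(int(sum(counts)))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _multiset_permutations(counts: list[int]):
    """All distinct label-index vectors with the given per-label counts,
    in lexicographic order."""
    n = sum(counts)
    vec = np.empty(n, dtype=np.int64)
    counts = list(counts)

    def rec(pos: int):
        if pos == n:
            yield vec.copy()
            return
        for c in range(len(counts)):
            if counts[c]:
                counts[c] -= 1
                vec[pos] = c
                yield from rec(pos + 1)
                counts[c] += 1

    yield from rec(0)


def sample_assignments(base: np.ndarray, n_permutations: int,
                       seed: int) -> list[np.ndarray]:
    """B independent shuffles of the sample-to-condition vector; one shared
    set is reused across all modules of a run so module p-values are
    comparable."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(base) for _ in range(n_permutations)]


def permutation_test(expr: ExpressionMatrix, labels: ConditionLabels,
                     module: NetworkModule, plan: PermutationPlan,
                     method: str = "pearson",
                     null_assignments: list[np.ndarray] | None = None
                     ) -> HubTestResult:
    """Permutation p-value for one module's differential-correlation
    statistic.

    ``null_assignments`` (sampled mode only) lets a caller share one set
    of permuted label vectors across modules; otherwise the plan's seed
    generates them.  Partners that become undefined under a particular
    permutation are dropped for that permutation only; if a permutation
    leaves no usable partner its null statistic is counted as extreme
    (>= observed), which is conservative.
    """
    _check_method(method)
    labels.validate_against(expr)
    conditions = labels.conditions
    n_cond = len(conditions)
    kind = "mean_difference" if n_cond == 2 else "anova_f"

    X, base = _module_matrix(expr, labels, module)
    base_cols = _group_cols(base, n_cond)
    corr = _corr_groups(X, base_cols, method)
    kept = np.isfinite(corr).all(axis=1)
    min_keep = 1 if kind == "mean_difference" else 2
    if kept.sum() < min_keep:
        raise DegenerateModuleError(
            f"module {module.hub}: fewer than {min_keep} partners with "
            "defined correlations in every condition")
    obs_corr = corr[kept]
    observed = (_mean_difference(obs_corr) if kind == "mean_difference"
                else _anova_f(obs_corr))
    mean_corr = {c: float(np.mean(obs_corr[:, ci]))
                 for ci, c in enumerate(conditions)}
    # null statistics are computed on the observed surviving partner set
    Xk = X[np.concatenate(([True], kept))]

    def null_stat(assignment: np.ndarray) -> float:
        cols = _group_cols(assignment, n_cond)
        return _stat_from_corr(_corr_groups(Xk, cols, method), kind)

    if plan.mode == "exhaustive":
        counts = np.bincount(base, minlength=n_cond)
        total = _count_assignments(counts)
        if total > plan.exhaustive_cap:
            raise ValueError(
                f"{total} distinct assignments exceed the exhaustive cap "
                f"({plan.exhaustive_cap}); use sampled mode")
        n_extreme = 0
        for vec in _multiset_permutations(list(counts)):
            stat = null_stat(vec)
            if np.isnan(stat) or stat >= observed:
                n_extreme += 1
        p_value = n_extreme / total
        n_perm_reported = total
    else:
        assignments = null_assignments
        if assignments is None:
            assignments = sample_assignments(base, plan.n_permutations,
                                             plan.seed)
        n_extreme = 0
        n_degenerate = 0
        for vec in assignments:
            stat = null_stat(vec)
            if np.isnan(stat):
                n_extreme += 1
                n_degenerate += 1
            elif stat >= observed:
                n_extreme += 1
        if n_degenerate:
            logger.debug("module %s: %d degenerate permutations counted as "
                         "extreme", module.hub, n_degenerate)
        p_value = (1 + n_extreme) / (len(assignments) + 1)
        n_perm_reported = len(assignments)

    return HubTestResult(
        hub=module.hub,
        n_partners=int(kept.sum()),
        mean_corr=mean_corr,
        statistic=float(observed),
        p_value=float(p_value),
        n_permutations=n_perm_reported,
        statistic_kind=kind,
    )


def identify_significant_hubs(expr: ExpressionMatrix, labels: ConditionLabels,
                              network: Network,
                              min_partners: int = DEFAULT_MIN_PARTNERS,
                              plan: PermutationPlan | None = None,
                              method: str = "pearson"
                              ) -> list[HubTestResult]:
    """Full single-dataset analysis: extract modules, test each one.

    One shared set of permuted label assignments (derived from the plan
    seed) is reused across all modules.  Modules that lose all usable
    partners are skipped with a warning.  A small p-value is evidence
    that the module's hub-partner co-expression structure differs across
    conditions.
    """
    if plan is None:
        raise ValueError("a PermutationPlan (with an explicit seed) is required")
    labels.validate_against(expr)
    modules = identify_hubs(network, expr, min_partners=min_partners)
    logger.info("evaluating %d modules (min_partners=%d, method=%s, B=%d, "
                "seed=%d, mode=%s)", len(modules), min_partners, method,
                plan.n_permutations, plan.seed, plan.mode)
    shared: list[np.ndarray] | None = None
    if plan.mode == "sampled" and modules:
        _, base = _module_matrix(expr, labels, modules[0])
        shared = sample_assignments(base, plan.n_permutations, plan.seed)
    results: list[HubTestResult] = []
    for module in modules:
        try:
            results.append(permutation_test(expr, labels, module, plan,
                                            method=method,
                                            null_assignments=shared))
        except DegenerateModuleError as exc:
            logger.warning("skipping module: %s", exc)
    if not results:
        logger.warning("no modules could be tested")
    return results
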