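"""Confirmation-stage statistics: one-way ANOVA and Dunnett's test.

Event frequencies of each treated group are compared against the vehicle
group by one-way ANOVA followed by Dunnett's many-to-one multiple-
comparison procedure.  The Dunnett adjustment is evaluated by seeded
Monte-Carlo sampling of the null max-|t| field — the (k-1) pairwise
t statistics against the shared control are equicorrelated through the
control group mean, with correlations set by the (possibly unbalanced)
group sizes — so unbalanced designs are handled exactly rather than
through balanced-table approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupSummary",
    "StatTestResult",
    "one_way_anova",
    "summarize_groups",
    "dunnett_t_statistics",
    "dunnett_null_sample",
    "dunnett_adjust",
    "anova_dunnett",
]


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    mean: float
    sem: float | None
    n: int
    t: float | None = None               # vs control; None for the control itself
    p_unadjusted: float | None = None
    p_adjusted: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class StatTestResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    per_group: tuple[GroupSummary, ...]


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(out):
        if g.size and not np.all(np.isfinite(g)):
            raise InputError(f"group {i} contains non-finite values")
    return out


def one_way_anova(groups) -> StatTestResult:
    """Classical one-way ANOVA over k groups.

    Raises on groups with n < 2, and on the degenerate case of zero
    within-group variance with equal means (F is 0/0).
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InputError("ANOVA needs at least two groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise InputError(f"group {i} has n={g.size} < 2")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    means = [g.mean() for g in gs]
    if ssw == 0.0 and np.ptp(means) == 0.0:
        raise InputError(
            "degenerate input: zero within-group variance with equal means"
        )
    f_stat, p = sps.f_oneway(*gs)
    return StatTestResult(
        F=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
        per_group=tuple(
            GroupSummary(group_id=str(i), mean=float(m), sem=_sem(g), n=g.size)
            for i, (g, m) in enumerate(zip(gs, means))
        ),
    )


def _sem(g: np.ndarray) -> float | None:
    if g.size < 2:
        return None
    return float(np.std(g, ddof=1) / np.sqrt(g.size))


def summarize_groups(groups, ids=None) -> list[GroupSummary]:
    """Mean +/- SEM per group; SEM is None for singleton groups."""
    gs = _as_groups(groups)
    if any(g.size < 1 for g in gs):
        raise InputError("every group needs at least one observation")
    if ids is None:
        ids = [str(i) for i in range(len(gs))]
    return [
        GroupSummary(group_id=str(gid), mean=float(g.mean()), sem=_sem(g), n=g.size)
        for gid, g in zip(ids, gs)
    ]


def dunnett_t_statistics(groups, control_index: int = 0) -> tuple[np.ndarray, float, int]:
    """Pooled-variance t statistics of each treatment vs the control.

    Returns (t for the k-1 non-control groups in order, pooled variance,
    within-group degrees of freedom).
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InputError("Dunnett needs at least two groups")
    if not 0 <= control_index < len(gs):
        raise InputError(f"control_index {control_index} out of range")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise InputError(f"group {i} has n={g.size} < 2")
    nu = sum(g.size for g in gs) - len(gs)
    s2 = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs) / nu
    if s2 <= 0:
        raise InputError("zero pooled within-group variance")
    ctrl = gs[control_index]
    ts = []
    for i, g in enumerate(gs):
        if i == control_index:
            continue
        se = np.sqrt(s2 * (1.0 / g.size + 1.0 / ctrl.size))
        ts.append((g.mean() - ctrl.mean()) / se)
    return np.asarray(ts), s2, nu


def dunnett_null_sample(
    sizes, control_index: int = 0, n_draws: int = 200_000, seed=0
) -> np.ndarray:
    """Monte-Carlo sample of the null max-|t| statistic of Dunnett's field.

    Each draw simulates group means as independent Gaussians with variance
    1/n_j and a shared pooled-variance chi-square with the design's
    within-group degrees of freedom — the exact joint law of the (k-1)
    equicorrelated t statistics under the global null.  Reusable across
    datasets that share the same group sizes.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 2 or np.any(sizes < 2):
        raise InputError("need >= 2 groups of size >= 2")
    if not 0 <= control_index < sizes.size:
        raise InputError(f"control_index {control_index} out of range")
    rng = np.random.default_rng(seed)
    nu = int(sizes.sum() - sizes.size)
    z = rng.standard_normal((n_draws, sizes.size)) / np.sqrt(sizes)
    s = np.sqrt(rng.chisquare(nu, n_draws) / nu)
    others = np.delete(np.arange(sizes.size), control_index)
    se = np.sqrt(1.0 / sizes[others] + 1.0 / sizes[control_index])
    t = (z[:, others] - z[:, [control_index]]) / (s[:, None] * se)
    return np.abs(t).max(axis=1)


def dunnett_adjust(
    groups,
    control_index: int = 0,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed=0,
    ids=None,
    null_sample: np.ndarray | None = None,
) -> list[GroupSummary]:
    """Two-sided Dunnett-adjusted p-values of each treatment vs the control.

    adjusted p = P(max_j |T_j| >= |t_i|) under the simulated null, clipped
    from below at the unadjusted pooled-t p-value so the multiplicity
    ordering (adjusted >= unadjusted) holds despite Monte-Carlo noise.
    The control's entry carries no test fields.
    """
    gs = _as_groups(groups)
    ts, _, nu = dunnett_t_statistics(gs, control_index)
    if ids is None:
        ids = [str(i) for i in range(len(gs))]
    if null_sample is None:
        null_sample = dunnett_null_sample(
            [g.size for g in gs], control_index, n_draws, seed
        )
    out: list[GroupSummary] = []
    j = 0
    for i, g in enumerate(gs):
        if i == control_index:
            out.append(
                GroupSummary(group_id=str(ids[i]), mean=float(g.mean()),
                             sem=_sem(g), n=g.size)
            )
            continue
        t = float(ts[j])
        j += 1
        p_un = float(2.0 * sps.t.sf(abs(t), nu))
        p_adj = float(np.mean(null_sample >= abs(t)))
        p_adj = min(1.0, max(p_adj, p_un))
        out.append(
            GroupSummary(
                group_id=str(ids[i]), mean=float(g.mean()), sem=_sem(g), n=g.size,
                t=t, p_unadjusted=p_un, p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out


def anova_dunnett(
    groups,
    control_index: int = 0,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed=0,
    ids=None,
) -> StatTestResult:
    """One-way ANOVA followed by Dunnett comparisons against the control."""
    anova = one_way_anova(groups)
    per_group = dunnett_adjust(
        groups, control_index=control_index, alpha=alpha,
        n_draws=n_draws, seed=seed, ids=ids,
    )
    return StatTestResult(
        F=anova.F,
        df_between=anova.df_between,
        df_within=anova.df_within,
        p_value=anova.p_value,
        per_group=tuple(per_group),
    )
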