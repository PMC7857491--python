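"""Group-level statistics: fold-changes, Dunnett's test, preference ranking.

Dunnett's many-to-one comparison is computed from first principles: the k
treatment-vs-control t statistics share the one-factor correlation induced
by the common control mean and the pooled variance estimate, and the
family-wise probability P(max|T| ≤ q) is evaluated by deterministic
Gauss–Hermite (control axis) × Gauss–Legendre (pooled-sd axis) quadrature
of the multivariate-t integral — no simulation, so adjusted p-values are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats

__all__ = [
    "GroupComparison", "DunnettResult",
    "fold_change", "dunnett_vs_control", "rank_preference", "significance_stars",
]


@dataclass
class GroupComparison:
    """Ratio of group means with a bootstrap confidence interval."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sem_a: float | None
    sem_b: float | None
    n_a: int
    n_b: int
    fold_change: float
    log2_fold_change: float
    ci_low: float
    ci_high: float
    ci_method: str
    negative_mean_flag: bool


@dataclass
class DunnettResult:
    """Single-step Dunnett many-to-one comparison against a control."""

    control: str
    labels: list
    statistics: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    df: int
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted < self.alpha

    @property
    def stars(self) -> list:
        return [significance_stars(p) for p in self.p_adjusted]


def significance_stars(p: float) -> str:
    """Four-tier star annotation: 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "ns"


def fold_change(group_a, group_b, label_a: str = "A", label_b: str = "B",
                n_boot: int = 2000, seed: int = 0,
                ci_level: float = 0.95) -> GroupComparison:
    """Ratio of mean(group_a)/mean(group_b) with a bootstrap percentile CI.

    Negative means are flagged (below-detection semantics) rather than
    rejected; a zero denominator mean is an error.
    """
    a = np.atleast_1d(np.asarray(group_a, dtype=float))
    b = np.atleast_1d(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if mb == 0:
        raise ZeroDivisionError("denominator group has zero mean")
    fc = ma / mb
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True).mean()
        rb = rng.choice(b, size=b.size, replace=True).mean()
        boots[i] = ra / rb if rb != 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    if boots.size:
        ci_low, ci_high = np.quantile(boots, [lo_q, hi_q])
        # degenerate resamples (e.g. single-value groups) collapse the CI;
        # keep it containing the point estimate
        ci_low, ci_high = min(ci_low, fc), max(ci_high, fc)
    else:
        ci_low = ci_high = fc
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size >= 2 else None
    return GroupComparison(
        label_a=label_a, label_b=label_b, mean_a=ma, mean_b=mb,
        sem_a=sem(a), sem_b=sem(b), n_a=a.size, n_b=b.size,
        fold_change=fc,
        log2_fold_change=float(np.log2(fc)) if fc > 0 else float("nan"),
        ci_low=float(ci_low), ci_high=float(ci_high),
        ci_method=f"bootstrap-percentile({n_boot}, seed={seed})",
        negative_mean_flag=bool(ma < 0 or mb < 0),
    )


@lru_cache(maxsize=32)
def _quad_nodes(df: int, n_z: int = 96, n_u: int = 192):
    xh, wh = hermgauss(n_z)
    z = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)
    xu, wu = leggauss(n_u)
    u = 0.5 * (xu + 1.0)
    wu = 0.5 * wu
    w = stats.chi.ppf(u, df) / np.sqrt(df)   # pooled sd / sigma
    return z, wz, w, wu


def _dunnett_prob(q, c: np.ndarray, df: int) -> np.ndarray:
    """P(max_i |T_i| <= q) for Dunnett's one-factor correlation structure.

    c_i = sqrt(n_i/(n_i+n_0)) is the loading of comparison i on the shared
    control axis; df is the pooled error degrees of freedom.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    z, wz, w, wu = _quad_nodes(df)
    s = np.sqrt(1.0 - c**2)                               # (k,)
    out = np.empty(q.shape)
    # grids: z (nz,), w (nu,), comparisons (k,)
    czs = (c[:, None] * z[None, :])                       # (k, nz)
    for j, qj in enumerate(q):
        qw = qj * w                                       # (nu,)
        upper = (qw[:, None, None] + czs.T[None, :, :]) / s[None, None, :]
        lower = (-qw[:, None, None] + czs.T[None, :, :]) / s[None, None, :]
        # (nu, nz, k)
        bracket = stats.norm.cdf(upper) - stats.norm.cdf(lower)
        prod = np.prod(bracket, axis=2)                   # (nu, nz)
        out[j] = float(wu @ prod @ wz)
    return np.clip(out, 0.0, 1.0)


def dunnett_vs_control(groups: dict, control: str, alpha: float = 0.05) -> DunnettResult:
    """One-way-ANOVA-style Dunnett comparison of every group to a control.

    Uses the pooled within-group variance (homogeneous-variance
    assumption) and two-sided single-step adjustment; handles unbalanced
    group sizes.  Deterministic: p-values come from quadrature of the
    multivariate-t probability (tolerance ~1e-6).
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} missing")
    labels = [g for g in groups if g != control]
    if not labels:
        raise ValueError("need at least one non-control group")
    arrays = {g: np.atleast_1d(np.asarray(v, dtype=float)) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    n0 = arrays[control].size
    df = int(sum(v.size for v in arrays.values()) - len(arrays))
    ss = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrays.values())
    s2 = ss / df
    m0 = float(arrays[control].mean())
    t_stats, c_load, p_unadj = [], [], []
    for g in labels:
        v = arrays[g]
        se = np.sqrt(s2 * (1.0 / v.size + 1.0 / n0))
        diff = float(v.mean()) - m0
        # zero pooled variance (exactly identical replicates): the test is
        # degenerate; report t = 0 for equal means, +-inf otherwise
        t = diff / se if se > 0 else (0.0 if diff == 0 else np.sign(diff) * np.inf)
        t_stats.append(t)
        c_load.append(np.sqrt(v.size / (v.size + n0)))
        p_unadj.append(2.0 * stats.t.sf(abs(t), df))
    t_stats = np.array(t_stats)
    c_load = np.array(c_load)
    p_adj = 1.0 - _dunnett_prob(np.abs(t_stats), c_load, df)
    p_adj = np.clip(np.maximum(p_adj, np.array(p_unadj)), 0.0, 1.0)
    return DunnettResult(
        control=control, labels=labels, statistics=t_stats,
        p_adjusted=p_adj, p_unadjusted=np.array(p_unadj),
        df=df, alpha=alpha,
    )


def rank_preference(activities_by_variant: dict) -> list[dict]:
    """Rank substrate variants by mean activity, flagging ties.

    Input values may be raw replicate arrays or ``(mean, sem)`` tuples.
    Variants are ordered by descending mean; adjacent variants whose
    mean ± SEM intervals overlap share a tie group rather than being
    arbitrarily split.
    """
    if not activities_by_variant:
        raise ValueError("no variants to rank")
    if len(activities_by_variant) < 2:
        raise ValueError("ranking needs >= 2 variants")
    stats_by = {}
    for label, v in activities_by_variant.items():
        if isinstance(v, tuple) and len(v) == 2 and np.isscalar(v[0]):
            mean, sem = float(v[0]), (float(v[1]) if v[1] is not None else 0.0)
        else:
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            mean = float(arr.mean())
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size >= 2 else 0.0
        stats_by[label] = (mean, sem)
    ordered = sorted(stats_by, key=lambda g: (-stats_by[g][0], g))
    out = []
    tie_group = 0
    for i, label in enumerate(ordered):
        mean, sem = stats_by[label]
        if i > 0:
            pm, ps = stats_by[ordered[i - 1]]
            overlap = (mean + sem) >= (pm - ps)
            if not overlap:
                tie_group += 1
        out.append({
            "variant": label, "rank": i + 1, "mean": mean, "sem": sem,
            "tie_group": tie_group,
            "tied_with_previous": i > 0 and tie_group == out[-1]["tie_group"],
        })
    return out
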