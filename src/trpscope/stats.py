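"""Group comparisons for the imaging readouts.

The headline statistic is a percentile-bootstrap confidence interval on the
ratio of group means, reported as a percentage of the reference group
("ipsilateral at X% of contralateral, 95% CI a-b%"): each of the (default)
10,000 resamples draws with replacement within each group independently and
records mean(target*) / mean(reference*) x 100.

Hypothesis-testing routes follow common practice for such data: a
Shapiro-Wilk normality gate chooses between parametric (one-way ANOVA with
Holm-Sidak step-down post-hoc) and non-parametric (Kruskal-Wallis with
Dunn's rank post-hoc, Holm-adjusted) paths; paired ipsi/contra designs use
the exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "bootstrap_ratio_ci",
    "shapiro_gate",
    "kruskal_dunn",
    "anova_holm_sidak",
    "wilcoxon_paired",
]


@dataclass
class GroupComparison:
    """Ratio-of-means estimate with percentile-bootstrap CI (percent)."""

    ratio_of_means_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n_boot: int
    level: float
    seed: int
    n_target: int
    n_reference: int
    p_value: float | None = None
    test_name: str = ""
    flags: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # the field's reporting style
        s = (
            f"{self.ratio_of_means_pct:.0f}% "
            f"(95% CI {self.ci_low_pct:.0f}% to {self.ci_high_pct:.0f}%)"
        )
        if self.p_value is not None:
            s += f"; {self.test_name} p={self.p_value:.3g}"
        return s


def bootstrap_ratio_ci(
    target: np.ndarray,
    reference: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> GroupComparison:
    """Percentile-bootstrap CI for mean(target)/mean(reference) x 100.

    Resampling is with replacement within each group independently (the
    groups are distinct cell populations, not pairs). Point estimate is the
    observed ratio of means. Requires >= 3 values per group and a positive
    reference mean; single-valued groups collapse the CI to the point and
    are flagged.
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(target) < 3 or len(reference) < 3:
        raise ValueError("both groups need >= 3 values")
    if reference.mean() <= 0:
        raise ValueError("reference group mean must be positive")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    flags = []
    if np.ptp(target) == 0 and np.ptp(reference) == 0:
        flags.append("degenerate: single-valued groups, CI collapses to point")
    t_idx = rng.integers(0, len(target), size=(n_boot, len(target)))
    r_idx = rng.integers(0, len(reference), size=(n_boot, len(reference)))
    t_means = target[t_idx].mean(axis=1)
    r_means = reference[r_idx].mean(axis=1)
    ok = r_means > 0
    if not ok.all():
        flags.append(f"{int((~ok).sum())} resamples with non-positive reference mean dropped")
    ratios = 100.0 * t_means[ok] / r_means[ok]
    alpha = 1 - level
    lo, hi = np.percentile(ratios, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    point = 100.0 * target.mean() / reference.mean()
    if not (lo <= point <= hi):
        flags.append("point estimate outside percentile CI")
    return GroupComparison(
        ratio_of_means_pct=float(point),
        ci_low_pct=float(lo),
        ci_high_pct=float(hi),
        n_boot=n_boot,
        level=level,
        seed=seed,
        n_target=len(target),
        n_reference=len(reference),
        flags=flags,
    )


def shapiro_gate(*groups: np.ndarray, alpha: float = 0.05) -> dict:
    """Choose the test family: non-parametric iff ANY group fails the
    Shapiro-Wilk normality test at ``alpha`` (or is too small/degenerate).

    Returns ``{"route": "parametric"|"nonparametric", "p_values": [...],
    "flags": [...]}``.
    """
    p_values: list[float] = []
    flags: list[str] = []
    route = "parametric"
    for k, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            flags.append(f"group {k}: n < 3, non-parametric by default")
            route = "nonparametric"
            p_values.append(np.nan)
            continue
        if np.ptp(g) == 0:
            flags.append(f"group {k}: constant sample, degenerate")
            route = "nonparametric"
            p_values.append(np.nan)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(g).pvalue)
        p_values.append(p)
        if p < alpha:
            route = "nonparametric"
    return {"route": route, "p_values": p_values, "flags": flags}


def _dunn_pairwise(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum z statistics for all pairs, with tie correction."""
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        )
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": i, "group_b": j, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def kruskal_dunn(groups: list[np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc (Holm-adjusted).

    Returns ``{"omnibus_p", "statistic", "pairwise": DataFrame, "flags"}``.
    All-tied data yields p = 1 with a flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    flags = []
    if np.ptp(np.concatenate(groups)) == 0:
        flags.append("all values tied")
        pairwise = _dunn_pairwise(groups)
        pairwise["p_adj"] = 1.0
        return {"omnibus_p": 1.0, "statistic": 0.0, "pairwise": pairwise, "flags": flags}
    stat, p = sps.kruskal(*groups)
    pairwise = _dunn_pairwise(groups)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return {
        "omnibus_p": float(p),
        "statistic": float(stat),
        "pairwise": pairwise,
        "flags": flags,
    }


def anova_holm_sidak(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA with Holm-Sidak step-down pairwise comparisons.

    Intended for per-animal summary values. Groups with a single value are
    excluded from the post-hoc stage and flagged. Adjusted p-values follow
    p_adj(i) = 1 - (1 - p_(i))^(m - i + 1) with enforced monotonicity.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    flags = []
    usable = [k for k, g in enumerate(groups) if len(g) >= 2]
    if len(usable) < len(groups):
        flags.append(
            f"groups {sorted(set(range(len(groups))) - set(usable))} have a "
            "single value: excluded from post-hoc"
        )
    stat, omnibus_p = sps.f_oneway(*[groups[k] for k in usable])
    rows = []
    for i, j in itertools.combinations(usable, 2):
        t, p = sps.ttest_ind(groups[i], groups[j])
        rows.append({"group_a": i, "group_b": j, "t": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="holm-sidak")[1]
    return {
        "omnibus_p": float(omnibus_p),
        "statistic": float(stat),
        "pairwise": pairwise,
        "flags": flags,
    }


def wilcoxon_paired(
    ipsi: np.ndarray, contra: np.ndarray, alternative: str = "two-sided"
) -> dict:
    """Exact paired Wilcoxon signed-rank test on ipsi - contra differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs. All-zero differences give p = 1 with a flag. Returns
    ``{"p", "statistic", "direction", "n_pairs", "flags"}`` where direction
    is the sign of the median difference.
    """
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    if len(ipsi) != len(contra):
        raise ValueError("paired samples must have equal length")
    diffs = ipsi - contra
    flags = []
    if np.all(diffs == 0):
        flags.append("all paired differences zero")
        return {
            "p": 1.0, "statistic": 0.0, "direction": 0,
            "n_pairs": len(diffs), "flags": flags,
        }
    nz = diffs[diffs != 0]
    method = "exact" if len(nz) <= 25 else "approx"
    res = sps.wilcoxon(
        nz, alternative=alternative, method=method, zero_method="wilcox"
    )
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "direction": int(np.sign(np.median(diffs))),
        "n_pairs": int(len(nz)),
        "flags": flags,
    }
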