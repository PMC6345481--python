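"""Inferential layer: repeated-measures ANOVA, post-hocs, correlations.

The central piece is a general fully-within-subject ANOVA for balanced
designs with any number of crossed within factors (here Task x Condition x
Band), with per-effect Greenhouse–Geisser sphericity correction and both
generalized (eta_G^2) and partial (eta_P^2) eta squared.  Two-factor
packages exist, but the three-factor within decomposition with per-effect
epsilon is built here from the classical sums-of-squares identities; each
effect is tested against its own subject-interaction error term.

Simple tests (paired t with d_z, Pearson r, Holm adjustment) delegate to
scipy/statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests


def expertise_index(weekly_practice_min: float, years_since_course: float) -> float:
    """Meditation expertise: weekly practice minutes x years since training."""
    if weekly_practice_min < 0 or years_since_course < 0:
        raise ValueError("practice minutes and years must be nonnegative")
    return float(weekly_practice_min * years_since_course)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    effect_size: float      # d_z for paired t, r for correlation
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


@dataclass
class AnovaResult:
    """One within-subject effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    epsilon: float          # Greenhouse–Geisser
    p_gg: float
    eta_g2: float
    eta_p2: float
    ss: float
    ss_error: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical paired t test with d_z = mean(diff)/sd(diff) = t/sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired_t needs two equal-length 1-d samples, n >= 2")
    n = x.size
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, n - 1, 1.0, 0.0, n)
        t = np.inf if d.mean() > 0 else -np.inf
        return TestResult(float(t), n - 1, 0.0, float(np.sign(d.mean()) * np.inf), n)
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), n - 1, float(p), float(t / np.sqrt(n)), n)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation with the two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_test needs two equal-length 1-d samples, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), x.size - 2, float(res.pvalue),
                      float(res.statistic), x.size)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Step-down Holm–Bonferroni adjustment, order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _check_balanced(table: pd.DataFrame, dv: str, subject: str, within: list[str]) -> None:
    counts = table.groupby([subject, *within], observed=True)[dv].count()
    subjects = table[subject].unique()
    level_sets = [np.unique(table[f]) for f in within]
    expected = {(s, *combo) for s in subjects
                for combo in itertools.product(*level_sets)}
    have = set(counts.index)
    missing = expected - have
    if missing:
        sample = sorted(missing)[:5]
        raise ValueError(
            f"unbalanced design: {len(missing)} missing cells, e.g. {sample}"
        )
    if (counts > 1).any():
        raise ValueError("design must have exactly one observation per cell")


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
) -> dict[str, AnovaResult]:
    """Fully-within-subject ANOVA for a balanced design.

    Parameters
    ----------
    table
        Long-format data with one row per subject x cell.
    dv
        Dependent-variable column.
    within
        Within-subject factor columns (1 or more, fully crossed).
    subject
        Subject identifier column.

    Returns a result per effect (main effects and all interactions), each
    tested against its own effect-by-subject error term.  The
    Greenhouse–Geisser epsilon is estimated per effect from the
    subject-level cell covariance through the effect's orthonormal
    contrast space, so two-level effects get epsilon = 1 exactly.
    eta_G^2 treats all factors as manipulated; eta_P^2 is
    SS_effect / (SS_effect + SS_error).
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within factor")
    _check_balanced(table, dv, subject, within)

    subjects = np.unique(table[subject])
    n = subjects.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    levels = [np.unique(table[f]) for f in within]
    sizes = [lv.size for lv in levels]

    wide = table.set_index([subject, *within])[dv].sort_index()
    y = wide.values.reshape(n, *sizes)          # (subject, f1, ..., fk)
    all_axes = tuple(range(y.ndim))

    def u_term(axes: tuple[int, ...]) -> float:
        """Sum over the margin of squared totals / cells summed."""
        other = tuple(a for a in all_axes if a not in axes)
        marg = y.sum(axis=other) if other else y
        n_summed = np.prod([y.shape[a] for a in other]) if other else 1
        return float(np.sum(np.asarray(marg) ** 2) / n_summed)

    u_cache = {(): float(y.sum() ** 2 / y.size)}

    def ss(axes: tuple[int, ...]) -> float:
        total = 0.0
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                if sub not in u_cache:
                    u_cache[sub] = u_term(sub)
                total += (-1) ** (len(axes) - r) * u_cache[sub]
        return total

    # subject-level cell covariance for the GG epsilon
    cells = y.reshape(n, -1)
    sigma = np.cov(cells.T) if cells.shape[1] > 1 else np.array([[cells.var(ddof=1)]])

    results: dict[str, AnovaResult] = {}
    factor_axes = list(range(1, y.ndim))
    effect_subsets = [
        combo
        for r in range(1, len(factor_axes) + 1)
        for combo in itertools.combinations(factor_axes, r)
    ]

    ss_subject = ss((0,))
    error_sum = ss_subject + sum(ss((0, *a)) for a in effect_subsets)

    for axes in effect_subsets:
        name = ":".join(within[a - 1] for a in axes)
        ss_eff = ss(axes)
        ss_err = ss((0, *axes))
        df_num = int(np.prod([sizes[a - 1] - 1 for a in axes]))
        df_den = (n - 1) * df_num
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_num, df_den)) if ms_err > 0 else 1.0

        # effect contrast: Helmert rows for in-effect factors, averages else
        C = np.ones((1, 1))
        for a in factor_axes:
            block = helmert(sizes[a - 1]) if a in axes else np.full(
                (1, sizes[a - 1]), 1.0 / sizes[a - 1]
            )
            C = np.kron(C, block)
        M = C @ sigma @ C.T
        d = df_num
        tr = np.trace(M)
        eps = float(tr**2 / (d * np.trace(M @ M))) if np.trace(M @ M) > 0 else 1.0
        eps = min(max(eps, 1.0 / d), 1.0)
        p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den)) if ms_err > 0 else 1.0

        eta_p2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        denom_g = ss_eff + error_sum
        eta_g2 = ss_eff / denom_g if denom_g > 0 else 0.0

        results[name] = AnovaResult(
            effect=name, F=float(F), df_num=df_num, df_den=df_den, p=p,
            epsilon=eps, p_gg=p_gg, eta_g2=float(eta_g2), eta_p2=float(eta_p2),
            ss=float(ss_eff), ss_error=float(ss_err),
        )
    return results


def anova_table(results: dict[str, AnovaResult]) -> pd.DataFrame:
    rows = [vars(r) for r in results.values()]
    return pd.DataFrame(rows).set_index("effect")


def mde_table_for(
    n_paired: int,
    n_corr: Sequence[int],
    alpha: float = 0.05,
    power: float = 0.80,
) -> pd.DataFrame:
    """Sensitivity (minimum detectable effect) table for the study's tests."""
    from .power import mde_correlation, mde_paired_t

    rows = []
    if n_paired >= 2:
        rows.append({"test": "paired_t", "n": n_paired, "alpha": alpha,
                     "power": power, "mde": mde_paired_t(n_paired, alpha, power)})
    for n in dict.fromkeys(int(n) for n in n_corr):
        if n >= 4:
            rows.append({"test": "correlation", "n": n, "alpha": alpha,
                         "power": power, "mde": mde_correlation(n, alpha, power)})
    return pd.DataFrame(rows)


def task_posthoc_by_band(
    table: pd.DataFrame,
    dv: str = "log_power",
    bands: Sequence[str] | None = None,
    subject: str = "subject",
) -> pd.DataFrame:
    """Per-band FAM vs IMW paired contrasts, Holm-adjusted within the family.

    The input is a long table with ``subject``, ``task``, ``band`` and the
    dependent variable (condition repetitions are averaged per subject).
    The family is the set of per-band contrasts (five under the default
    band scheme).
    """
    if bands is None:
        bands = list(pd.unique(table["band"]))
    per_cell = (
        table.groupby([subject, "task", "band"], observed=True)[dv].mean().reset_index()
    )
    rows = []
    for band in bands:
        sub = per_cell[per_cell["band"] == band].pivot(
            index=subject, columns="task", values=dv
        )
        res = paired_t(sub["IMW"].values, sub["FAM"].values)
        rows.append(
            {"band": band, "t": res.statistic, "df": res.df, "p_raw": res.p,
             "d_z": res.effect_size, "mean_diff": float(np.mean(sub["IMW"] - sub["FAM"]))}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].tolist())
    return out
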