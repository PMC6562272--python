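"""Statistical procedures for the contingency-learning analyses.

The central routine is a mixed-design (split-plot) repeated-measures
ANOVA: one between-subject factor (group) crossed with one
within-subject factor (programmed contingency level), every subject
measured at every level.  Sums of squares follow the classical
univariate decomposition

    SS_total = SS_group + SS_subjects(group)           (between-subject)
             + SS_level + SS_group×level + SS_error    (within-subject)

with the group effect tested against subjects-within-groups and the
within effects against the within error.  Sphericity of the within
covariance is assessed with Mauchly's test on the pooled within-group
covariance matrix; when it rejects (and the factor has more than two
levels) the within-effect p values are corrected with Greenhouse–Geisser
ε when ε_GG < 0.75 and Huynh–Feldt ε otherwise.  Effect sizes are
generalised η² with all subject-level variance in the denominator,

    η²_G = SS_effect / (SS_effect + SS_subjects(group) + SS_error),

which is comparable across designs.

Fisher's-LSD error bars for within-subject comparisons are half-widths
0.5 · t_(1−α/2, n−1) · SD(d̄), where SD(d̄) = sd(differences)/√n is the
standard deviation of the mean within-subject condition difference.
With that definition two bars fail to overlap exactly when the paired
t-test between the conditions rejects at α — the property these bars
exist to convey.  (Readings that use the raw difference SD instead do
not have this equivalence.)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "FlsdBar",
    "WelchResult",
    "MauchlyResult",
    "welch_t",
    "levene_test",
    "sphericity_epsilons",
    "mauchly_test",
    "mixed_anova",
    "simple_effects",
    "flsd_half_width",
    "flsd_bars",
    "drop_incomplete_subjects",
]

#: Mauchly-test level that triggers sphericity correction.
SPHERICITY_ALPHA = 0.05
#: ε_GG below which Greenhouse–Geisser (rather than Huynh–Feldt) is used.
GG_THRESHOLD = 0.75


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of an ANOVA table."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    p_corrected: float
    epsilon_gg: float
    epsilon_hf: float
    correction_used: str  # "none" | "GG" | "HF"
    ges: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class FlsdBar:
    """A condition mean with its FLSD half-width."""

    condition: float
    mean: float
    half_width: float


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class MauchlyResult:
    W: float
    chi2: float
    df: int
    p: float


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Both samples need n ≥ 2.  Two constant, equal samples return the
    t = 0 convention rather than NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per sample")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("both samples constant with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def levene_test(*samples: Sequence[float]) -> tuple[float, float]:
    """Levene's test for homogeneity of variance (median-centred)."""
    stat, p = sps.levene(*samples)
    return float(stat), float(p)


def _check_covariance(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    if cov.shape[0] < 2:
        raise ValueError("need at least 2 within-subject levels")
    return cov


def _centred_eigenvalues(cov: np.ndarray) -> np.ndarray:
    """Eigenvalues of the double-centred covariance (the population
    estimate relevant to sphericity); the structural zero is dropped."""
    k = cov.shape[0]
    centred = (
        cov
        - cov.mean(axis=0, keepdims=True)
        - cov.mean(axis=1, keepdims=True)
        + cov.mean()
    )
    eig = np.linalg.eigvalsh(centred)[1:]  # smallest (structural 0) removed
    return eig


def sphericity_epsilons(
    cov: np.ndarray, n_subjects: int, n_groups: int = 1
) -> tuple[float, float]:
    """Greenhouse–Geisser and Huynh–Feldt ε for a within covariance.

    ε_GG = (Σλ)² / ((k−1)·Σλ²) over the eigenvalues λ of the
    double-centred covariance, bounded in [1/(k−1), 1].  ε_HF rescales
    ε_GG using the error degrees of freedom n_e = n_subjects − n_groups
    and may exceed 1 (it is capped at 1 when applied to a test).
    """
    cov = _check_covariance(cov)
    k = cov.shape[0]
    d = k - 1
    if k == 2:
        return 1.0, 1.0
    eig = _centred_eigenvalues(cov)
    eig = eig[eig > 1e-12 * max(eig.max(), 1.0)]
    if eig.size == 0:
        warnings.warn(
            "singular within covariance; epsilon set to its lower bound",
            RuntimeWarning,
        )
        return 1.0 / d, 1.0 / d
    gg = float(eig.sum() ** 2 / (d * (eig**2).sum()))
    gg = min(1.0, max(1.0 / d, gg))
    n_e = n_subjects - n_groups
    denom = d * (n_e - d * gg)
    if denom <= 0:
        hf = 1.0
    else:
        hf = ((n_e + 1) * d * gg - 2.0) / denom
    hf = max(hf, 1.0 / d)
    return gg, float(hf)


def mauchly_test(
    cov: np.ndarray, n_subjects: int, n_groups: int = 1
) -> MauchlyResult:
    """Mauchly's test of sphericity on a within-subject covariance.

    Uses the eigenvalues of the double-centred covariance and the
    chi-square approximation with error df n_e = n_subjects − n_groups.
    A singular covariance yields W = NaN, p = NaN with a warning (the
    sphericity step is skipped).
    """
    cov = _check_covariance(cov)
    k = cov.shape[0]
    d = k - 1
    if k == 2:
        return MauchlyResult(W=1.0, chi2=0.0, df=1, p=1.0)
    ddof = int(d * (d + 1) / 2 - 1)
    eig = _centred_eigenvalues(cov)
    tol = np.finfo(float).eps * max(eig.max(), 0.0) * d
    pos = eig[eig > tol]
    if pos.size < d:
        warnings.warn(
            "singular within covariance; Mauchly's test skipped",
            RuntimeWarning,
        )
        return MauchlyResult(W=math.nan, chi2=math.nan, df=ddof, p=math.nan)
    W = float(np.prod(pos) / (pos.sum() / d) ** d)
    logW = math.log(W)
    n_e = n_subjects - n_groups
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * n_e)
    w2 = (
        (d + 2)
        * (d - 1)
        * (d - 2)
        * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * (n_e * d * f) ** 2)
    )
    chi2 = -n_e * f * logW
    p1 = sps.chi2.sf(chi2, ddof)
    p2 = sps.chi2.sf(chi2, ddof + 4)
    p = float(p1 + w2 * (p2 - p1))
    return MauchlyResult(W=W, chi2=float(chi2), df=ddof, p=p)


def _f_p(F: float, df1: float, df2: float) -> float:
    if df2 <= 0:
        return math.nan
    return float(sps.f.sf(F, df1, df2))


def _safe_f(ss_eff: float, df_eff: float, ss_err: float, df_err: float) -> float:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err == 0.0:
        return 0.0 if ms_eff <= 1e-300 else math.inf
    return ms_eff / ms_err


def _pivot_wide(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> tuple[np.ndarray, np.ndarray, list]:
    """Wide subject × level matrix; errors name any missing cell."""
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found in data")
    groups_per_subject = data.groupby(subject, sort=True)[between].nunique()
    multi = groups_per_subject[groups_per_subject > 1]
    if len(multi):
        raise ValueError(
            f"subject(s) {list(multi.index)} appear in more than one group"
        )
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", sort=True
    )
    if wide.isna().any().any():
        missing = [
            (subj, lvl)
            for subj in wide.index
            for lvl in wide.columns
            if pd.isna(wide.loc[subj, lvl])
        ]
        raise ValueError(f"missing within-factor cells: {missing[:10]}")
    group_of = data.groupby(subject, sort=True)[between].first()
    labels = group_of.loc[wide.index].to_numpy()
    return wide.to_numpy(dtype=float), labels, list(wide.columns)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    *,
    alpha_sphericity: float = SPHERICITY_ALPHA,
) -> list[AnovaResult]:
    """Split-plot ANOVA of a long-format measures table.

    Parameters
    ----------
    data : DataFrame
        Long format: one row per subject × within level.
    dv, within, between, subject : str
        Column names of the dependent variable, within factor (e.g.
        contingency level), between factor (group) and subject id.
    alpha_sphericity : float
        Mauchly level below which within-effect p values are corrected.

    Returns
    -------
    list of AnovaResult
        Effects in order: between (group), within, interaction.

    Notes
    -----
    Requires every subject at every within level (a missing cell raises
    with its subject and level named).  With unequal group sizes the
    weighted-means (hierarchical) decomposition is used; see the module
    docstring.
    """
    Y, labels, levels = _pivot_wide(data, dv, within, between, subject)
    n_total, k = Y.shape
    group_names, group_idx = np.unique(labels, return_inverse=True)
    a = len(group_names)
    if a < 2:
        raise ValueError("mixed_anova needs at least 2 groups")
    if k < 2:
        raise ValueError("mixed_anova needs at least 2 within levels")
    n_j = np.bincount(group_idx)
    if n_j.min() < 2:
        raise ValueError("every group needs at least 2 subjects")

    gm = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array(
        [Y[group_idx == j].mean() for j in range(a)]
    )
    level_means = Y.mean(axis=0)
    cell_means = np.array(
        [Y[group_idx == j].mean(axis=0) for j in range(a)]
    )  # a × k

    ss_total = float(((Y - gm) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - gm) ** 2).sum())
    ss_group = float(k * (n_j * (group_means - gm) ** 2).sum())
    ss_subjects = ss_between_subj - ss_group
    ss_level = float(n_total * ((level_means - gm) ** 2).sum())
    inter_dev = (
        cell_means
        - group_means[:, None]
        - level_means[None, :]
        + gm
    )
    ss_inter = float((n_j[:, None] * inter_dev**2).sum())
    ss_error = ss_total - ss_group - ss_subjects - ss_level - ss_inter
    ss_error = max(ss_error, 0.0)

    df_group = a - 1
    df_subj = n_total - a
    df_level = k - 1
    df_inter = (a - 1) * (k - 1)
    df_error = (n_total - a) * (k - 1)

    # pooled within-group covariance of the within levels
    pooled = np.zeros((k, k))
    for j in range(a):
        yj = Y[group_idx == j]
        pooled += (len(yj) - 1) * np.cov(yj, rowvar=False)
    pooled /= n_total - a

    eps_gg, eps_hf = sphericity_epsilons(pooled, n_total, a)
    mauchly = mauchly_test(pooled, n_total, a)

    def ges(ss_eff: float) -> float:
        denom = ss_eff + ss_subjects + ss_error
        return ss_eff / denom if denom > 0 else 0.0

    results: list[AnovaResult] = []

    F_g = _safe_f(ss_group, df_group, ss_subjects, df_subj)
    p_g = _f_p(F_g, df_group, df_subj)
    results.append(
        AnovaResult(
            effect=between,
            F=F_g,
            df_num=df_group,
            df_den=df_subj,
            p_uncorrected=p_g,
            p_corrected=p_g,
            epsilon_gg=math.nan,
            epsilon_hf=math.nan,
            correction_used="none",
            ges=ges(ss_group),
            ss_effect=ss_group,
            ss_error=ss_subjects,
        )
    )

    correct = (
        k > 2
        and not math.isnan(mauchly.p)
        and mauchly.p < alpha_sphericity
    )
    if correct:
        if eps_gg < GG_THRESHOLD:
            eps_used, correction = eps_gg, "GG"
        else:
            eps_used, correction = min(eps_hf, 1.0), "HF"
    else:
        eps_used, correction = 1.0, "none"

    for name, ss_eff, df_eff in (
        (within, ss_level, df_level),
        (f"{between} × {within}", ss_inter, df_inter),
    ):
        F = _safe_f(ss_eff, df_eff, ss_error, df_error)
        p_unc = _f_p(F, df_eff, df_error)
        p_cor = (
            _f_p(F, df_eff * eps_used, df_error * eps_used)
            if correction != "none"
            else p_unc
        )
        results.append(
            AnovaResult(
                effect=name,
                F=F,
                df_num=df_eff,
                df_den=df_error,
                p_uncorrected=p_unc,
                p_corrected=p_cor,
                epsilon_gg=eps_gg,
                epsilon_hf=eps_hf,
                correction_used=correction,
                ges=ges(ss_eff),
                ss_effect=ss_eff,
                ss_error=ss_error,
            )
        )
    return results


def simple_effects(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    at_level,
) -> AnovaResult:
    """One-way between-groups ANOVA at a single within-factor level.

    Used to follow up a significant interaction: is there a group
    difference at this contingency level?  η²_G here coincides with
    classical η² (SS_effect over SS_total of the restricted data).
    """
    levels = data[within].unique()
    if at_level not in levels:
        raise ValueError(
            f"level {at_level!r} not present in {within!r} (has {sorted(levels)})"
        )
    sub = data[data[within] == at_level]
    values = sub.groupby(subject, sort=True)[dv].mean()
    labels = sub.groupby(subject, sort=True)[between].first()
    y = values.to_numpy(dtype=float)
    group_names, group_idx = np.unique(labels.to_numpy(), return_inverse=True)
    a = len(group_names)
    if a < 2:
        raise ValueError("simple_effects needs at least 2 groups")
    n = len(y)
    gm = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for j in range(a):
        yj = y[group_idx == j]
        ss_between += len(yj) * (yj.mean() - gm) ** 2
        ss_within += ((yj - yj.mean()) ** 2).sum()
    df_b, df_w = a - 1, n - a
    F = _safe_f(ss_between, df_b, ss_within, df_w)
    p = _f_p(F, df_b, df_w)
    total = ss_between + ss_within
    return AnovaResult(
        effect=f"{between} @ {within}={at_level}",
        F=F,
        df_num=df_b,
        df_den=df_w,
        p_uncorrected=p,
        p_corrected=p,
        epsilon_gg=math.nan,
        epsilon_hf=math.nan,
        correction_used="none",
        ges=ss_between / total if total > 0 else 0.0,
        ss_effect=float(ss_between),
        ss_error=float(ss_within),
    )


def flsd_half_width(
    sample_a: Sequence[float],
    sample_b: Optional[Sequence[float]] = None,
    *,
    alpha: float = 0.05,
) -> float:
    """FLSD half-width for a within-subject condition comparison.

    Pass either the paired samples of two conditions, or directly the
    vector of within-subject differences.  Returns
    0.5 · t_(1−α/2, n−1) · sd(differences)/√n; two condition means drawn
    with this half-width overlap exactly when the paired t-test at α
    fails to reject.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    a = np.asarray(sample_a, dtype=float)
    if sample_b is not None:
        b = np.asarray(sample_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        diffs = a - b
    else:
        diffs = a
    n = diffs.size
    if n < 2:
        raise ValueError("flsd_half_width requires n >= 2 subjects")
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, n - 1)
    se = diffs.std(ddof=1) / math.sqrt(n)
    return float(0.5 * t_crit * se)


def flsd_bars(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    *,
    alpha: float = 0.05,
) -> list[FlsdBar]:
    """Condition means with FLSD half-widths for plotting.

    The half-width shown at each condition is the mean of the pairwise
    half-widths involving its neighbouring conditions (single pair at
    the ends), so adjacent-bar overlap reads as the adjacent paired
    test.
    """
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", sort=True
    ).dropna()
    levels = list(wide.columns)
    if len(levels) < 2:
        raise ValueError("flsd_bars needs at least 2 conditions")
    pair_hw = {}
    for left, right in zip(levels[:-1], levels[1:]):
        pair_hw[(left, right)] = flsd_half_width(
            wide[left].to_numpy(), wide[right].to_numpy(), alpha=alpha
        )
    bars = []
    for i, lvl in enumerate(levels):
        hws = []
        if i > 0:
            hws.append(pair_hw[(levels[i - 1], lvl)])
        if i < len(levels) - 1:
            hws.append(pair_hw[(lvl, levels[i + 1])])
        bars.append(
            FlsdBar(
                condition=lvl,
                mean=float(wide[lvl].mean()),
                half_width=float(np.mean(hws)),
            )
        )
    return bars


def drop_incomplete_subjects(
    data: pd.DataFrame, dv: str, subject: str
) -> tuple[pd.DataFrame, int]:
    """Listwise-drop subjects with any missing value of ``dv``.

    Returns the filtered frame and the number of subjects removed; used
    before an ANOVA when the dependent variable can be undefined (e.g.
    experienced probabilities in never-press blocks).
    """
    bad = data.loc[data[dv].isna(), subject].unique()
    kept = data[~data[subject].isin(bad)].copy()
    return kept, len(bad)
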