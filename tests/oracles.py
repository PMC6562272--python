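"""Independent brute-force oracles for the statistics routines.

These compute ANOVA sums of squares by a different route than the
package: sequential least-squares fits of nested dummy-coded linear
models, taking residual-sum-of-squares drops as each term enters.  For
the split-plot design (group between, level within, complete data) this
hierarchical decomposition is the classical weighted-means analysis the
package implements in closed form from cell means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def _rss(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    X = np.column_stack(blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def splitplot_ss(
    df: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> dict[str, float]:
    """Sequential-OLS sums of squares of the split-plot decomposition."""
    y = df[dv].to_numpy(dtype=float)
    one = np.ones(len(df))
    gd = pd.get_dummies(df[between]).to_numpy(float)
    sd = pd.get_dummies(df[subject]).to_numpy(float)
    ld = pd.get_dummies(df[within]).to_numpy(float)
    inter = np.stack(
        [gd[:, i] * ld[:, j] for i in range(gd.shape[1]) for j in range(ld.shape[1])],
        axis=1,
    )
    r0 = _rss(y, [one])
    r1 = _rss(y, [one, gd])
    r2 = _rss(y, [one, gd, sd])
    r3 = _rss(y, [one, gd, sd, ld])
    r4 = _rss(y, [one, gd, sd, ld, inter])
    return {
        "ss_group": r0 - r1,
        "ss_subjects": r1 - r2,
        "ss_within": r2 - r3,
        "ss_interaction": r3 - r4,
        "ss_error": r4,
        "ss_total": r0,
    }


def splitplot_f(
    df: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> dict[str, tuple[float, float]]:
    """(F, p) per effect from the oracle SS, uncorrected."""
    ss = splitplot_ss(df, dv, within, between, subject)
    a = df[between].nunique()
    k = df[within].nunique()
    n = df[subject].nunique()
    df_g, df_s = a - 1, n - a
    df_w, df_i, df_e = k - 1, (a - 1) * (k - 1), (n - a) * (k - 1)
    out = {}
    f_g = (ss["ss_group"] / df_g) / (ss["ss_subjects"] / df_s)
    out["group"] = (f_g, float(sps.f.sf(f_g, df_g, df_s)))
    mse = ss["ss_error"] / df_e
    f_w = (ss["ss_within"] / df_w) / mse
    out["within"] = (f_w, float(sps.f.sf(f_w, df_w, df_e)))
    f_i = (ss["ss_interaction"] / df_i) / mse
    out["interaction"] = (f_i, float(sps.f.sf(f_i, df_i, df_e)))
    return out


def oneway_f(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """(F, p, eta²) of a one-way between ANOVA, via residual fits."""
    y = np.concatenate(groups)
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(groups)]
    )
    one = np.ones(len(y))
    gd = pd.get_dummies(labels).to_numpy(float)
    r0 = _rss(y, [one])
    r1 = _rss(y, [one, gd])
    ss_b, ss_w = r0 - r1, r1
    df_b, df_w = len(groups) - 1, len(y) - len(groups)
    F = (ss_b / df_b) / (ss_w / df_w)
    return F, float(sps.f.sf(F, df_b, df_w)), ss_b / r0
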