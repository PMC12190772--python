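"""Statistical layer: outlier screening, group contrasts, correlations with
FDR control, the alpha-modulation contrast, and semi-partial correlations.

Subjects are screened per parameter with Tukey fences (1.5 IQR beyond the
quartiles) and excluded when extreme in more than a configurable number of
microstate-parameter cells (default > 3 across the 4 temporal parameters x
states) or transition-probability cells (default > 4). Correlation families
are Benjamini-Hochberg-adjusted with a configurable family size. The
semi-partial correlation removes the control variable's influence from the
microstate parameter only, then correlates the residual with the clinical
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StatResult",
    "flag_outlier_subjects",
    "group_compare",
    "correlate",
    "fdr_bh",
    "alpha_modulation",
    "semipartial_corr",
    "build_report",
]

logger = logging.getLogger(__name__)

MS_PARAMS = ("coverage", "occurrence", "duration", "gev")


@dataclass
class StatResult:
    """One test's report: statistic, df, p, effect size, n."""

    statistic: float
    df: float
    p_value: float
    effect_size: float
    n: int
    effect_name: str = "d"
    p_adjusted: float | None = None


def _tukey_extreme(col: pd.Series) -> pd.Series:
    """True where a value lies beyond the 1.5 IQR fences of its column.

    A zero-width IQR (constant column) flags nothing.
    """
    q1, q3 = col.quantile(0.25), col.quantile(0.75)
    iqr = q3 - q1
    if iqr == 0:
        return pd.Series(False, index=col.index)
    return (col < q1 - 1.5 * iqr) | (col > q3 + 1.5 * iqr)


def flag_outlier_subjects(
    table: pd.DataFrame,
    ms_instance_limit: int = 3,
    tp_instance_limit: int = 4,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Exclusion masks for microstate and transition-probability analyses.

    A subject is excluded from microstate analyses when extreme (Tukey
    fences) in strictly more than ``ms_instance_limit`` of the
    parameter x state cells, and from TP analyses when extreme in strictly
    more than ``tp_instance_limit`` TP cells. Returns (ms_excluded,
    tp_excluded, per-subject extreme counts).
    """
    if len(table) < 4:
        raise ValueError("quartiles undefined with fewer than 4 subjects")
    ms_cols = [
        c for c in table.columns if any(c.startswith(p + "_") for p in MS_PARAMS)
    ]
    tp_cols = [c for c in table.columns if c.startswith("tp_")]
    ms_counts = (
        pd.concat([_tukey_extreme(table[c]) for c in ms_cols], axis=1).sum(axis=1)
        if ms_cols else pd.Series(0, index=table.index)
    )
    tp_counts = (
        pd.concat([_tukey_extreme(table[c]) for c in tp_cols], axis=1).sum(axis=1)
        if tp_cols else pd.Series(0, index=table.index)
    )
    ms_excluded = ms_counts > ms_instance_limit
    tp_excluded = tp_counts > tp_instance_limit
    if ms_excluded.any() or tp_excluded.any():
        logger.info(
            "outlier screen: %d MS exclusions, %d TP exclusions",
            int(ms_excluded.sum()), int(tp_excluded.sum()),
        )
    counts = pd.DataFrame({"ms_extreme_cells": ms_counts, "tp_extreme_cells": tp_counts})
    return ms_excluded, tp_excluded, counts


def group_compare(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-sample t test with pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    d = (x.mean() - y.mean()) / pooled
    return StatResult(
        statistic=float(t), df=float(nx + ny - 2), p_value=float(p),
        effect_size=float(d), n=nx + ny, effect_name="d",
    )


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> StatResult:
    """Pearson or Spearman correlation with two-tailed p; NaN pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(
        statistic=float(r), df=float(len(x) - 2), p_value=float(p),
        effect_size=float(r), n=len(x), effect_name=method[0] if method == "pearson" else "rho",
    )


def fdr_bh(pvals: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` lets the nominal family be larger than the supplied
    vector (tests dropped for missing data still count toward the family);
    it defaults to ``len(pvals)`` and may not be smaller.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = family_size if family_size is not None else p.size
    if m < p.size:
        raise ValueError("family_size cannot be smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def alpha_modulation(
    table: pd.DataFrame,
    ms_parameter: str,
    states: list[str],
    group_col: str = "group",
    alpha_col: str = "alpha_power",
) -> StatResult:
    """OLS contrast for alpha power's effect on a microstate parameter.

    The parameter is mean-centered within state, stacked across states, and
    regressed on alpha power plus group; the alpha-power slope is reported
    with its F (= t²) and p. A deliberately simple fixed-effects counterpart
    of a state-random-intercept mixed model.
    """
    cols = [f"{ms_parameter}_{s}" for s in states]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    sub = table[np.isfinite(table[alpha_col])]
    if len(sub) < 10:
        raise ValueError("need alpha power for at least 10 subjects")
    frames = []
    for c in cols:
        frames.append(
            pd.DataFrame(
                {
                    "y": sub[c] - sub[c].mean(),
                    "alpha": sub[alpha_col],
                    "grp": (sub[group_col] == "ASD").astype(float),
                }
            )
        )
    stacked = pd.concat(frames, ignore_index=True).dropna()
    if stacked["alpha"].std() == 0:
        raise ValueError("alpha power is constant; slope undefined")
    X = sm.add_constant(stacked[["alpha", "grp"]])
    fit = sm.OLS(stacked["y"], X).fit()
    t = float(fit.tvalues["alpha"])
    return StatResult(
        statistic=t * t, df=float(fit.df_resid), p_value=float(fit.pvalues["alpha"]),
        effect_size=float(fit.params["alpha"]), n=len(stacked), effect_name="slope",
    )


def semipartial_corr(
    table: pd.DataFrame,
    ms_parameter: str,
    clinical_score: str,
    control: str = "alpha_power",
) -> StatResult:
    """Semi-partial correlation: control removed from the MS parameter only.

    The microstate parameter is residualized on the control by least squares
    (with intercept); the residual is then Pearson-correlated with the
    clinical score. p is two-tailed on n - 3 degrees of freedom.
    """
    cols = table[[ms_parameter, clinical_score, control]].dropna()
    if len(cols) < 4:
        raise ValueError("semi-partial correlation needs n >= 4 complete triples")
    x = cols[ms_parameter].to_numpy(dtype=float)
    y = cols[clinical_score].to_numpy(dtype=float)
    z = cols[control].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("clinical score has zero variance")
    Z = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(Z, x, rcond=None)
    resid = x - Z @ beta
    if resid.std() < 1e-14 * max(x.std(), 1e-300):
        raise ValueError("control explains the MS parameter perfectly")
    r = float(np.corrcoef(resid, y)[0, 1])
    n = len(cols)
    df = n - 3  # one control variable partialled out
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(
        statistic=r, df=float(df), p_value=p, effect_size=r, n=n, effect_name="semi-r"
    )


def build_report(
    features: pd.DataFrame,
    states: list[str],
    clinical_scores: list[str] | None = None,
    fdr_family_size: int = 6,
    ms_instance_limit: int = 3,
    tp_instance_limit: int = 4,
) -> dict[str, pd.DataFrame]:
    """Assemble the full statistics bundle from a subject feature table.

    Returns a dict of DataFrames: ``group_contrasts`` (per MS parameter and
    TP entry, t/p/d), ``correlations`` (zero-order r and semi-r side by side
    per parameter x clinical score, BH-adjusted within each score's family),
    ``exclusions`` (outlier screen counts and flags).
    """
    if features.empty:
        raise ValueError("empty feature table")
    for required in ("group",):
        if required not in features.columns:
            raise KeyError(f"feature table lacks required column {required!r}")
    ms_excl, tp_excl, counts = flag_outlier_subjects(
        features, ms_instance_limit, tp_instance_limit
    )
    exclusions = counts.copy()
    exclusions["ms_excluded"] = ms_excl
    exclusions["tp_excluded"] = tp_excl

    ms_cols = [
        c for c in features.columns
        if any(c.startswith(p + "_") for p in MS_PARAMS) or c in ("alpha_power", "alpha_cf")
    ]
    tp_cols = [c for c in features.columns if c.startswith("tp_")]

    contrast_rows = []
    for col in ms_cols + tp_cols:
        keep = ~(tp_excl if col in tp_cols else ms_excl)
        sub = features[keep]
        td = sub.loc[sub["group"] == "TD", col].to_numpy(dtype=float)
        asd = sub.loc[sub["group"] == "ASD", col].to_numpy(dtype=float)
        try:
            res = group_compare(td, asd)
        except ValueError:
            continue
        contrast_rows.append(
            {
                "parameter": col, "t": res.statistic, "df": res.df,
                "p": res.p_value, "cohens_d": res.effect_size, "n": res.n,
            }
        )
    group_contrasts = pd.DataFrame(contrast_rows)

    corr_rows = []
    if clinical_scores:
        clin = features[features["group"] == "ASD"]
        param_cols = [
            f"{p}_{s}" for p in MS_PARAMS for s in states if f"{p}_{s}" in features.columns
        ]
        for score in clinical_scores:
            if score not in clin.columns:
                continue
            method = "spearman" if score.endswith("_total") else "pearson"
            batch = []
            for col in param_cols:
                sub = clin[~ms_excl.reindex(clin.index, fill_value=True)]
                try:
                    zero = correlate(sub[col], sub[score], method=method)
                    semi = semipartial_corr(sub, col, score)
                except (ValueError, KeyError):
                    continue
                batch.append(
                    {
                        "parameter": col, "score": score, "method": method,
                        "r": zero.statistic, "p": zero.p_value,
                        "semi_r": semi.statistic, "semi_p": semi.p_value,
                        "n": zero.n,
                    }
                )
            if batch:
                df_b = pd.DataFrame(batch)
                m = max(fdr_family_size, len(df_b))
                df_b["p_fdr"] = fdr_bh(df_b["p"].to_numpy(), family_size=m)
                df_b["semi_p_fdr"] = fdr_bh(df_b["semi_p"].to_numpy(), family_size=m)
                corr_rows.append(df_b)
    correlations = (
        pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame()
    )
    return {
        "group_contrasts": group_contrasts,
        "correlations": correlations,
        "exclusions": exclusions,
    }
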