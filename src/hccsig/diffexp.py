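"""Per-gene statistical engines.

Fixed-effects two-way ANOVA with interaction (vectorized across genes via
projection model comparison — Type II sums of squares, which coincide with
Type I/III on the balanced designs this study uses), one-way ANOVA, unpaired
t-tests, linear-scale fold changes, and binary-template matching (Pearson
correlation of a gene's profile against an idealized condition template,
with the exact t-transform p-value).

ANOVA and t statistics act on log2 intensities; fold changes on the linear
scale.  Untestable genes (no variance) propagate as missing, never as p = 1.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleDesign, ValidationError

_REL_TOL = 1e-12


def _hat(x: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the column space of x."""
    return x @ np.linalg.pinv(x)


def _rss(y: np.ndarray, hat: np.ndarray) -> np.ndarray:
    resid = y - y @ hat.T
    return np.einsum("ij,ij->i", resid, resid)


def two_way_anova(log_matrix: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Per-gene two-factor ANOVA (treatment, age, interaction).

    Returns one row per gene with F and p per term plus the sums of squares
    and degrees of freedom.  On a balanced design the term SS plus residual
    SS reproduce the total SS exactly (to numerical tolerance).
    """
    dt = design.table.loc[log_matrix.columns]
    treatment = dt["treatment"].to_numpy()
    age = dt["age"].to_numpy()
    t_levels = sorted(set(treatment))
    a_levels = sorted(set(age))
    if len(t_levels) < 2 or len(a_levels) < 2:
        raise ValidationError("two_way_anova needs >= 2 levels of both factors")
    cells = sorted({(t, a) for t, a in zip(treatment, age)})
    cell_counts = {c: int(np.sum((treatment == c[0]) & (age == c[1]))) for c in cells}
    testable_design = all(v >= 2 for v in cell_counts.values())

    n = len(treatment)
    y = log_matrix.to_numpy(dtype=float)
    ones = np.ones((n, 1))
    t_ind = np.column_stack([(treatment == lv).astype(float) for lv in t_levels])
    a_ind = np.column_stack([(age == lv).astype(float) for lv in a_levels])
    cell_ind = np.column_stack(
        [((treatment == t) & (age == a)).astype(float) for t, a in cells]
    )

    df_t = len(t_levels) - 1
    df_a = len(a_levels) - 1
    df_int = (len(cells) - 1) - df_t - df_a
    df_res = n - len(cells)

    index = log_matrix.index
    out = pd.DataFrame(index=index)
    if not testable_design or df_res <= 0:
        for term in ("treatment", "age", "interaction"):
            out[f"F_{term}"] = np.nan
            out[f"p_{term}"] = np.nan
            out[f"ss_{term}"] = np.nan
        out["ss_residual"] = np.nan
        out["ss_total"] = np.nan
        out["df_treatment"], out["df_age"], out["df_interaction"], out["df_residual"] = (
            df_t,
            df_a,
            df_int,
            df_res,
        )
        return out

    counts = np.array(list(cell_counts.values()), dtype=float)
    balanced = len(set(cell_counts.values())) == 1

    grand = y.mean(axis=1)
    t_counts = t_ind.sum(axis=0)
    a_counts = a_ind.sum(axis=0)
    t_means = (y @ t_ind) / t_counts
    a_means = (y @ a_ind) / a_counts
    cell_means = (y @ cell_ind) / counts
    fitted_full = cell_means @ cell_ind.T
    ss_res = np.einsum("ij,ij->i", y - fitted_full, y - fitted_full)
    ss_total = np.einsum("ij,ij->i", y - grand[:, None], y - grand[:, None])

    if balanced:
        # closed-form balanced decomposition from marginal and cell means
        ss_treat = ((t_means - grand[:, None]) ** 2 * t_counts).sum(axis=1)
        ss_age = ((a_means - grand[:, None]) ** 2 * a_counts).sum(axis=1)
        t_of_cell = np.array([t_levels.index(t) for t, _ in cells])
        a_of_cell = np.array([a_levels.index(a) for _, a in cells])
        inter_dev = (
            cell_means
            - t_means[:, t_of_cell]
            - a_means[:, a_of_cell]
            + grand[:, None]
        )
        ss_int = (inter_dev**2 * counts).sum(axis=1)
    else:
        # unbalanced: Type II via model comparison on projections
        rss_t = _rss(y, _hat(np.hstack([ones, t_ind[:, 1:]])))
        rss_a = _rss(y, _hat(np.hstack([ones, a_ind[:, 1:]])))
        rss_add = _rss(y, _hat(np.hstack([ones, t_ind[:, 1:], a_ind[:, 1:]])))
        ss_treat = np.maximum(rss_a - rss_add, 0.0)
        ss_age = np.maximum(rss_t - rss_add, 0.0)
        ss_int = np.maximum(rss_add - ss_res, 0.0)
    ss_res = np.maximum(ss_res, 0.0)

    scale = np.maximum(ss_total, 1.0)
    degenerate_total = ss_total <= _REL_TOL * n  # essentially constant gene
    zero_resid = ss_res <= _REL_TOL * scale

    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / df_res
        for term, ss, df in (
            ("treatment", ss_treat, df_t),
            ("age", ss_age, df_a),
            ("interaction", ss_int, df_int),
        ):
            f = (ss / df) / ms_res
            p = stats.f.sf(f, df, df_res)
            # zero within-cell variance: the limit F -> inf if the term moves
            # any cell mean, else the null F of 0
            term_present = ss > _REL_TOL * scale
            f = np.where(zero_resid, np.where(term_present, np.inf, 0.0), f)
            p = np.where(zero_resid, np.where(term_present, 0.0, 1.0), p)
            f = np.where(degenerate_total, np.nan, f)
            p = np.where(degenerate_total, np.nan, p)
            out[f"F_{term}"] = f
            out[f"p_{term}"] = p
            out[f"ss_{term}"] = ss
    out["ss_residual"] = ss_res
    out["ss_total"] = ss_total
    out["df_treatment"], out["df_age"], out["df_interaction"], out["df_residual"] = (
        df_t,
        df_a,
        df_int,
        df_res,
    )
    return out


def one_way_anova(log_matrix: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Classical one-way F-test per gene across the treatment levels."""
    dt = design.table.loc[log_matrix.columns]
    groups = []
    for level in sorted(set(dt["treatment"])):
        ids = list(dt.index[dt["treatment"] == level])
        if len(ids) < 2:
            raise ValidationError(f"treatment group {level!r} has < 2 samples")
        groups.append(log_matrix[ids].to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValidationError("one_way_anova needs >= 2 treatment groups")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; they come
        # out as NaN/1.0 and are handled downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.f_oneway(*groups, axis=1)
    return pd.DataFrame({"F": res.statistic, "p": res.pvalue}, index=log_matrix.index)


def unpaired_t(
    log_matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided unpaired t-test per gene; Welch variances by default."""
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("unpaired_t requires >= 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            log_matrix[a].to_numpy(dtype=float),
            log_matrix[b].to_numpy(dtype=float),
            axis=1,
            equal_var=equal_var,
        )
    return pd.DataFrame({"t": res.statistic, "p": res.pvalue}, index=log_matrix.index)


def fold_change(
    linear_matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Ratio of arithmetic group means on the linear intensity scale.

    ``abs_fc = max(ratio, 1/ratio) >= 1``; direction UP iff mean A > mean B.
    """
    mean_a = linear_matrix[list(group_a)].mean(axis=1)
    mean_b = linear_matrix[list(group_b)].mean(axis=1)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValidationError("fold_change requires positive group means (apply a floor)")
    ratio = mean_a / mean_b
    abs_fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1.0, "UP", "DOWN")
    return pd.DataFrame(
        {"ratio": ratio, "abs_fc": abs_fc, "direction": direction},
        index=linear_matrix.index,
    )


def template_match(log_matrix: pd.DataFrame, template: Sequence[float]) -> pd.DataFrame:
    """Pearson correlation of each gene's profile with a binary template.

    The template marks target-condition samples with 1 and all others with 0
    (both values must occur).  p is the exact two-sided t-transform of r with
    n - 2 degrees of freedom; direction follows sign(r).  Constant profiles
    are untestable (missing r/p).
    """
    t = np.asarray(template, dtype=float)
    if t.shape[0] != log_matrix.shape[1]:
        raise ValidationError("template length must equal the number of samples")
    if len(np.unique(t)) < 2:
        raise ValidationError("template is constant: both template values must occur")
    n = t.shape[0]
    y = log_matrix.to_numpy(dtype=float)
    yc = y - y.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.sqrt(np.einsum("ij,ij->i", yc, yc)) * np.sqrt(tc @ tc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ tc) / denom
    r = np.clip(r, -1.0, 1.0)
    constant = denom <= 0
    r[constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[constant] = np.nan
    direction = np.where(np.isnan(r), "", np.where(r > 0, "UP", "DOWN"))
    return pd.DataFrame({"r": r, "p": p, "direction": direction}, index=log_matrix.index)
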