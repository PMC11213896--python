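"""Normalisation, filtering and adjustment of omics matrices.

All quantile computations use linear interpolation between order statistics
(numpy's default, the "type 7" rule); standard deviations use the n-1
denominator.  These conventions are applied consistently across the package.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, ZScoreMatrix
from .stats import build_design

logger = logging.getLogger(__name__)

__all__ = [
    "replace_zeros",
    "median_normalize",
    "mask_outliers_iqr",
    "adjust_covariates",
    "zscore_vs_controls",
    "log2_transform",
]


def replace_zeros(m: OmicsMatrix, rng: np.random.Generator) -> OmicsMatrix:
    """Replace zero intensities with draws from Uniform(0, 0.5 * min non-zero).

    The bound is computed per feature; non-zero values are untouched.
    Features that are entirely zero cannot be imputed and are dropped with a
    warning.
    """
    vals = m.values.copy()
    arr = vals.to_numpy(float)
    all_zero = []
    for i, fid in enumerate(vals.index):
        row = arr[i]
        zeros = row == 0
        if not zeros.any():
            continue
        nonzero = row[(row != 0) & ~np.isnan(row)]
        if len(nonzero) == 0:
            all_zero.append(fid)
            continue
        bound = 0.5 * float(np.min(np.abs(nonzero)))
        arr[i, zeros] = rng.uniform(0.0, bound, size=int(zeros.sum()))
    out = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    if all_zero:
        logger.warning("replace_zeros: dropping %d all-zero features: %s",
                       len(all_zero), all_zero[:5])
        out = out.drop(index=all_zero)
    return OmicsMatrix(out, m.layer, m.units)


def median_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each sample by (global median intensity) / (sample median).

    The global median is taken over all finite entries of the matrix pooled
    together.  After normalisation every sample median equals the global
    median, so the operation is idempotent.
    """
    arr = m.values.to_numpy(float)
    global_median = float(np.nanmedian(arr))
    sample_medians = np.nanmedian(arr, axis=0)
    bad = np.where(~(sample_medians > 0))[0]
    if len(bad):
        names = [str(m.sample_ids[i]) for i in bad]
        raise ValueError(f"non-positive sample medians: {names[:5]}")
    scaled = arr * (global_median / sample_medians)[None, :]
    return OmicsMatrix(pd.DataFrame(scaled, index=m.feature_ids, columns=m.sample_ids),
                       m.layer, m.units)


def mask_outliers_iqr(m: OmicsMatrix, groups: pd.Series, k: float = 3.0,
                      min_group: int = 4) -> OmicsMatrix:
    """Mask extreme outliers per feature within each sample group.

    Within every group (typically karyotype), values strictly below
    Q1 - k*IQR or above Q3 + k*IQR are set missing.  Quartiles use linear
    interpolation; groups with fewer than ``min_group`` non-missing values
    for a feature are skipped.
    """
    vals = m.values.copy()
    arr = vals.to_numpy(float)
    n_masked = 0
    n_skipped = 0
    for g in pd.unique(groups):
        cols = np.array([c in set(groups.index[groups == g]) for c in vals.columns])
        if not cols.any():
            continue
        block = arr[:, cols]
        for i in range(block.shape[0]):
            row = block[i]
            ok = ~np.isnan(row)
            if ok.sum() < min_group:
                n_skipped += 1
                continue
            q1, q3 = np.percentile(row[ok], [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            bad = ok & ((row < lo) | (row > hi))
            if bad.any():
                n_masked += int(bad.sum())
                row[bad] = np.nan
        arr[:, cols] = block
    if n_masked or n_skipped:
        logger.info("mask_outliers_iqr: masked %d values; skipped %d feature-groups",
                    n_masked, n_skipped)
    return OmicsMatrix(pd.DataFrame(arr, index=vals.index, columns=vals.columns),
                       m.layer, m.units)


def adjust_covariates(m: OmicsMatrix, samples: pd.DataFrame, covariates) -> OmicsMatrix:
    """Remove fitted covariate contributions from a log2-scale matrix.

    Per feature, OLS of value on the covariates (categoricals reference-
    coded, numerics centered); the fitted non-intercept contributions are
    subtracted so the grand mean is retained.  An empty covariate list is
    the identity.
    """
    covariates = list(covariates)
    if not covariates:
        return m.copy()
    sub = samples.loc[list(m.sample_ids)]
    X, names = build_design(sub, covariates)
    Y = m.values.to_numpy(float)
    adjusted = np.array(Y)
    complete = ~np.isnan(Y).any(axis=1)
    Xc = X[:, 1:]  # covariate columns only (exclude intercept)
    if complete.any():
        beta = np.linalg.lstsq(X, Y[complete].T, rcond=None)[0]
        adjusted[complete] = Y[complete] - (Xc @ beta[1:]).T
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(Y[i])
        if ok.sum() <= X.shape[1]:
            continue
        beta = np.linalg.lstsq(X[ok], Y[i][ok], rcond=None)[0]
        adjusted[i, ok] = Y[i][ok] - X[ok][:, 1:] @ beta[1:]
    return OmicsMatrix(pd.DataFrame(adjusted, index=m.feature_ids, columns=m.sample_ids),
                       m.layer, m.units)


def zscore_vs_controls(m: OmicsMatrix, reference) -> ZScoreMatrix:
    """Standardise each feature against a reference sample group.

    z = (x - mean_ref) / sd_ref with the sample SD (n-1).  Features whose
    reference SD is zero (or undefined) are dropped with a warning.
    """
    reference = [s for s in reference]
    if not reference:
        raise ValueError("reference sample set is empty")
    missing = [s for s in reference if s not in m.values.columns]
    if missing:
        raise KeyError(f"reference samples absent from matrix: {missing[:5]}")
    ref = m.values[reference]
    mean = ref.mean(axis=1, skipna=True)
    sd = ref.std(axis=1, ddof=1, skipna=True)
    bad = ~(sd > 0)
    if bad.any():
        logger.warning("zscore_vs_controls: dropping %d features with zero reference SD",
                       int(bad.sum()))
    keep = ~bad
    z = m.values.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ZScoreMatrix(z=z, reference=tuple(reference), ref_mean=mean[keep],
                        ref_sd=sd[keep], layer=m.layer)


def log2_transform(m: OmicsMatrix, pseudocount: float = 0.0) -> OmicsMatrix:
    """Elementwise log2(x + pseudocount); rejects non-positive shifted values."""
    arr = m.values.to_numpy(float) + pseudocount
    if np.nanmin(arr) <= 0:
        raise ValueError("log2_transform: non-positive values after pseudocount shift")
    out = pd.DataFrame(np.log2(arr), index=m.feature_ids, columns=m.sample_ids)
    return OmicsMatrix(out, m.layer, f"log2({m.units}+{pseudocount})" if m.units else "log2")
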