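"""Feature filtering, log2 transform, QC-based correction, Pareto scaling.

The correction stage inverts the two technical artefacts a pooled-QC design
can measure: a linear within-batch signal drift along the injection order and
a constant between-batch offset. Both are estimated per compound from the QC
injections only and subtracted from every sample of the batch, so biological
contrasts are untouched by construction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import AbundanceMatrix, biological_mask
from .exceptions import DataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "filter_features",
    "log2_transform",
    "qc_correct",
    "pareto_scale",
    "QCDriftCorrector",
    "ParetoScaler",
]


def filter_features(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    min_present: int = 3,
    mode: str = "any_group",
):
    """Replicate-presence filter on the raw matrix.

    A compound is retained iff at least one biological variety x week group
    has >= ``min_present`` non-missing replicates (``mode="any_group"``,
    the default) or iff every group in which it appears at all satisfies
    this (``mode="all_groups"``). Returns ``(filtered_matrix, removed_ids)``.
    """
    if matrix.scale != "raw":
        raise ValidationError(f"filter_features expects a raw-scale matrix, got {matrix.scale!r}")
    if mode not in ("any_group", "all_groups"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    bio = samples[biological_mask(samples)]
    group_sizes = bio.groupby(["variety", "cultivation", "harvest_week_index"]).size()
    if min_present > int(group_sizes.max()):
        raise ValidationError(
            f"min_present={min_present} exceeds the largest replicate group ({int(group_sizes.max())})"
        )
    present = matrix.data.loc[bio["sample_id"]].notna()
    keys = list(zip(bio["variety"], bio["cultivation"], bio["harvest_week_index"]))
    counts = present.groupby(pd.Index(keys)).sum()  # groups x compounds
    if mode == "any_group":
        keep = (counts >= min_present).any(axis=0)
    else:
        appears = counts > 0
        keep = ((counts >= min_present) | ~appears).all(axis=0) & appears.any(axis=0)
    removed = matrix.compounds[~keep].tolist()
    if removed:
        logger.info("filter_features removed %d compounds", len(removed))
    out = matrix.with_data(matrix.data.loc[:, keep[keep].index])
    out.meta = dict(matrix.meta, removed_compounds=removed)
    return out, removed


def log2_transform(matrix: AbundanceMatrix, offset: float = 0.0) -> AbundanceMatrix:
    """Cell-wise log2; missing cells stay missing.

    Reconstructed MS intensities are strictly positive in practice, so no
    pseudo-count is added by default; zero or negative present values raise
    with a pointer to the ``offset`` option.
    """
    if matrix.scale != "raw":
        raise ValidationError(f"log2_transform expects a raw-scale matrix, got {matrix.scale!r}")
    vals = matrix.data.to_numpy(dtype=float) + offset
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValidationError(
            "matrix contains non-positive present values; pass a positive `offset` "
            "(e.g. half the smallest positive intensity) to log2_transform"
        )
    out = pd.DataFrame(np.log2(vals), index=matrix.samples, columns=matrix.compounds)
    return matrix.with_data(out, scale="log2")


class QCDriftCorrector(TransformerMixin, BaseEstimator):
    """Remove within-batch linear drift and between-batch offsets using QCs.

    Per compound and batch, a least-squares line of the QC log2 values on the
    injection order is fitted and subtracted from every sample in the batch,
    centred so the batch QC mean is preserved; each batch is then shifted so
    its QC mean equals the grand QC mean. Batches with fewer than
    ``min_qc=2`` usable QC values for a compound fall back to median
    alignment (logged in ``fallback_log_``); with none, the batch is left
    unchanged for that compound.

    Parameters
    ----------
    min_qc:
        Minimum usable QC measurements per batch x compound for the linear
        drift fit.

    Attributes
    ----------
    slopes_ : DataFrame (batch x compound) fitted drift slopes (log2/injection).
    shifts_ : DataFrame (batch x compound) additive batch alignment offsets.
    qc_centers_ : DataFrame (batch x compound) mean QC injection order.
    fallback_log_ : list of (batch, compound, reason) tuples.
    """

    def __init__(self, min_qc: int = 2):
        self.min_qc = min_qc

    def fit(self, X: pd.DataFrame, samples: pd.DataFrame):
        samples = samples.set_index("sample_id", drop=False).loc[X.index]
        qc = samples["is_qc"].astype(bool)
        if not qc.any():
            raise DataError("no QC rows found; QC-based correction is impossible")

        batches = list(dict.fromkeys(samples["batch"]))
        compounds = X.columns
        slopes = pd.DataFrame(0.0, index=batches, columns=compounds)
        centers = pd.DataFrame(0.0, index=batches, columns=compounds)
        batch_means = pd.DataFrame(np.nan, index=batches, columns=compounds)
        fallback: list[tuple] = []

        for b in batches:
            in_batch = samples["batch"] == b
            qc_rows = in_batch & qc
            Y = X.loc[qc_rows].to_numpy(dtype=float)
            t = samples.loc[qc_rows, "injection_order"].to_numpy(dtype=float)
            M = ~np.isnan(Y)
            n_ok = M.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                tbar = (t[:, None] * M).sum(axis=0) / n_ok
                dev = (t[:, None] - tbar) * M
                denom = (dev**2).sum(axis=0)
                slope = (dev * np.nan_to_num(Y)).sum(axis=0) / denom
                ymean = np.nansum(np.where(M, Y, 0.0), axis=0) / n_ok
            linear_ok = (n_ok >= self.min_qc) & (denom > 0)
            slope = np.where(linear_ok, slope, 0.0)
            tbar = np.where(linear_ok, tbar, 0.0)
            for ci in np.nonzero(~linear_ok)[0]:
                if n_ok[ci] >= 1:
                    fallback.append((b, compounds[ci], "median_alignment"))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        ymean[ci] = np.nanmedian(Y[:, ci])
                else:
                    fallback.append((b, compounds[ci], "no_usable_qc"))
                    ymean[ci] = np.nan
            slopes.loc[b] = slope
            centers.loc[b] = tbar
            batch_means.loc[b] = ymean

        grand = batch_means.mean(axis=0, skipna=True)
        shifts = batch_means.sub(grand, axis=1).fillna(0.0)

        self.slopes_ = slopes
        self.shifts_ = shifts
        self.qc_centers_ = centers
        self.grand_qc_mean_ = grand
        self.fallback_log_ = fallback
        self._sample_meta = samples[["batch", "injection_order"]]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        meta = self._sample_meta
        unknown = [s for s in X.index if s not in meta.index]
        if unknown:
            raise DataError(f"sample {unknown[0]!r} was not seen during fit")
        cols = [c for c in X.columns if c in self.slopes_.columns]
        if len(cols) != X.shape[1]:
            raise DataError("matrix columns do not match the fitted compounds")
        batch = meta.loc[X.index, "batch"]
        order = meta.loc[X.index, "injection_order"].to_numpy(dtype=float)
        slope = self.slopes_.loc[batch, cols].to_numpy()
        center = self.qc_centers_.loc[batch, cols].to_numpy()
        shift = self.shifts_.loc[batch, cols].to_numpy()
        corrected = X.to_numpy(dtype=float) - slope * (order[:, None] - center) - shift
        return pd.DataFrame(corrected, index=X.index, columns=X.columns)


def qc_correct(matrix: AbundanceMatrix, samples: pd.DataFrame, min_qc: int = 2) -> AbundanceMatrix:
    """Functional wrapper around :class:`QCDriftCorrector` (fit and apply)."""
    if matrix.scale not in ("log2", "corrected"):
        raise ValidationError(f"qc_correct expects a log2-scale matrix, got {matrix.scale!r}")
    corrector = QCDriftCorrector(min_qc=min_qc).fit(matrix.data, samples)
    out = matrix.with_data(corrector.transform(matrix.data), scale="corrected")
    out.meta = dict(matrix.meta, qc_fallbacks=corrector.fallback_log_)
    return out


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Mean-centre each compound and divide by the square root of its SD.

    Pareto scaling damps the dominance of high-variance compounds in PCA
    while keeping the data's variance ordering (unlike unit-variance
    scaling). Compounds with zero variance are dropped with a warning.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if X.notna().sum(axis=0).min() < 1:
            empty = X.columns[X.notna().sum(axis=0) < 1][0]
            raise ValidationError(f"compound {empty!r} has no observed values; filter first")
        self.means_ = X.mean(axis=0, skipna=True)
        sd = X.std(axis=0, ddof=1, skipna=True)
        zero = sd.isna() | (sd == 0)
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} constant compound(s) during Pareto scaling",
                stacklevel=2,
            )
        self.dropped_ = X.columns[zero].tolist()
        self.scales_ = np.sqrt(sd[~zero])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = [c for c in X.columns if c not in set(self.dropped_)]
        return (X[keep] - self.means_[keep]) / self.scales_[keep]


def pareto_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Functional wrapper around :class:`ParetoScaler`."""
    if matrix.scale not in ("log2", "corrected"):
        raise ValidationError(f"pareto_scale expects log2/corrected data, got {matrix.scale!r}")
    scaler = ParetoScaler().fit(matrix.data)
    return matrix.with_data(scaler.transform(matrix.data), scale="pareto")
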