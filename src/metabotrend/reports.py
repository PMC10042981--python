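"""Exploratory and reporting outputs: fold-change matrices, HCA, PCA,
flavour-compound panel, and per-time-point variety x cultivation contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .datatypes import AbundanceMatrix, biological_mask
from .exceptions import DataError, ValidationError
from .preprocess import ParetoScaler
from .simulate import FLAVOUR_PANEL
from .trend import EFFECTS, FitResult, PriorEstimate, bh_adjust, estimate_prior

logger = logging.getLogger(__name__)

__all__ = [
    "LogFCResult",
    "compute_logfc",
    "truncate_logfc",
    "hca_order",
    "pca_scores",
    "flavour_report",
    "cultivation_model",
]


@dataclass
class LogFCResult:
    """Per-compound weekly log fold changes relative to each series' first week."""

    matrix: pd.DataFrame        # compounds x (variety, cultivation, week)
    excluded: list              # compounds with >= missing_cutoff missing cells
    missing_cutoff: float


def compute_logfc(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    missing_cutoff: float = 0.90,
) -> LogFCResult:
    """Average log2 abundance per variety x week minus the first-week average.

    Cells where the first sampled week of a series has no observed value for
    a compound carry no FC (NaN). Compounds missing in >= ``missing_cutoff``
    of all biological cells are excluded entirely and listed.
    """
    if matrix.scale not in ("log2", "corrected"):
        raise ValidationError(f"compute_logfc expects log2/corrected data, got {matrix.scale!r}")
    bio = samples[biological_mask(samples)]
    data = matrix.data.loc[bio["sample_id"]]

    frac_missing = data.isna().mean(axis=0)
    excluded = data.columns[frac_missing >= missing_cutoff].tolist()
    kept = data.columns[frac_missing < missing_cutoff]
    if excluded:
        logger.info("compute_logfc: %d compounds excluded (>=%.0f%% missing)", len(excluded), 100 * missing_cutoff)

    keys = pd.DataFrame(
        {
            "variety": bio["variety"].to_numpy(),
            "cultivation": bio["cultivation"].to_numpy(),
            "week": bio["harvest_week_index"].astype(int).to_numpy(),
        },
        index=data.index,
    )
    grouped = data[kept].groupby(
        [keys["variety"], keys["cultivation"], keys["week"]]
    ).mean()  # (variety, cultivation, week) x compounds
    blocks = []
    for (v, c), sub in grouped.groupby(level=[0, 1], sort=True):
        sub = sub.sort_index(level=2)
        first = sub.iloc[0]
        fc = sub.sub(first, axis=1)
        fc.index = pd.MultiIndex.from_tuples(
            [(v, c, w) for (_, _, w) in sub.index], names=["variety", "cultivation", "week"]
        )
        blocks.append(fc)
    out = pd.concat(blocks).T
    out.index.name = "compound_id"
    return LogFCResult(matrix=out, excluded=excluded, missing_cutoff=missing_cutoff)


def truncate_logfc(matrix: pd.DataFrame, lo: float = -6.0, hi: float = 6.0) -> pd.DataFrame:
    """Clamp a display copy of the FC matrix to [lo, hi]."""
    if lo >= hi:
        raise ValidationError(f"truncation bounds must satisfy lo < hi, got ({lo}, {hi})")
    return matrix.clip(lower=lo, upper=hi)


def hca_order(matrix: pd.DataFrame, min_pairs: int = 3):
    """Average-linkage HCA of compounds with correlation distance.

    Distance = 1 - Pearson correlation over pairwise-complete columns.
    Compounds with zero variance or fewer than ``min_pairs`` complete pairs
    against some other compound are dropped with a warning. Returns
    ``(ordered_ids, linkage_matrix, kept_ids)``.
    """
    sd = matrix.std(axis=1, ddof=0)
    keep = sd[sd > 0].index
    if len(keep) < len(matrix):
        warnings.warn(f"dropping {len(matrix) - len(keep)} zero-variance compound(s) from HCA", stacklevel=2)
    sub = matrix.loc[keep]
    corr = sub.T.corr(min_periods=min_pairs)
    complete = corr.notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} compound(s) with <{min_pairs} complete pairs from HCA",
            stacklevel=2,
        )
        corr = corr.loc[complete, complete]
    kept = corr.index.tolist()
    if len(kept) < 2:
        raise DataError("fewer than 2 compounds usable for HCA")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = average(squareform(dist, checks=False))
    order = [kept[i] for i in leaves_list(Z)]
    return order, Z, kept


def pca_scores(matrix: AbundanceMatrix, n_components: int = 5):
    """PCA of the Pareto-scaled matrix (QC rows projected with the rest).

    Missing cells are imputed with the compound's minimum observed log2
    value (left-censoring rationale) before scaling. Returns
    ``(scores, loadings, explained_fractions)``; explained fractions are
    non-increasing and sum to <= 1.
    """
    if matrix.scale == "pareto":
        scaled = matrix.data
    else:
        if matrix.scale not in ("log2", "corrected"):
            raise ValidationError(f"pca_scores expects log2/corrected/pareto data, got {matrix.scale!r}")
        imputed = matrix.data.apply(lambda col: col.fillna(col.min()), axis=0)
        scaled = ParetoScaler().fit(imputed).transform(imputed)
    X = scaled.to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # per-compound centring (no-op after Pareto)
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncated", stacklevel=2)
        n_components = rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (X**2).sum()
    explained = (s**2 / total_var)[:n_components]
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * s[:n_components], index=scaled.index, columns=pcs)
    loadings = pd.DataFrame(Vt[:n_components].T, index=scaled.columns, columns=pcs)
    return scores, loadings, explained


def flavour_report(
    curves: pd.DataFrame,
    stats: pd.DataFrame,
    classes: pd.Series,
    compounds: pd.DataFrame,
    panel=FLAVOUR_PANEL,
    fold_threshold: float = 1.0,
) -> tuple[pd.DataFrame, list]:
    """Seasonal-trend report for the configured sensory-relevant compounds.

    Panel entries are matched against compound annotations (case
    insensitive), independent of their significance. Per matched compound
    the report carries its effect class, the maximum modelled |logFC|,
    whether the trend stays within the 2-fold band (|logFC| <= 1) for every
    variety and week, the weeks crossing the band, and whether any pointwise
    CI excludes zero. Unmatched panel entries are returned as not detected.
    """
    ann = compounds.set_index("compound_id")["annotation"].astype(str).str.lower()
    rows, not_detected = [], []
    for name in panel:
        match = ann[ann == name.lower()]
        if match.empty:
            not_detected.append(name)
            continue
        cid = match.index[0]
        sub = curves[curves["compound_id"] == cid]
        if sub.empty:
            not_detected.append(name)
            continue
        max_abs = sub["logfc"].abs().max()
        crossing = sub[sub["logfc"].abs() > fold_threshold]
        crossing_weeks = sorted(set(zip(crossing["variety"], crossing["week"])))
        ci_excl = bool(((sub["ci_lo"] > 0) | (sub["ci_hi"] < 0)).any())
        rows.append(
            {
                "panel_name": name,
                "compound_id": cid,
                "effect_class": classes.get(cid, "unfitted"),
                "max_abs_logfc": max_abs,
                "within_2fold": bool(max_abs <= fold_threshold),
                "crossing_weeks": ";".join(f"{v}:w{w}" for v, w in crossing_weeks),
                "ci_excludes_zero": ci_excl,
            }
        )
    return pd.DataFrame(rows), not_detected


def cultivation_model(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    time_point: int,
    min_replicates: int = 2,
    span: float = 0.5,
) -> pd.DataFrame:
    """Variety x cultivation one-way moderated F-test at one calendar week.

    All varieties harvested in calendar week ``time_point`` are compared
    with a fixed effect per variety x cultivation group; the residual
    variances are moderated against the subset's own ensemble before the
    F-test, and p-values are BH adjusted.
    """
    if matrix.scale not in ("log2", "corrected"):
        raise ValidationError(f"cultivation_model expects log2/corrected data, got {matrix.scale!r}")
    bio = samples[biological_mask(samples)]
    sub = bio[bio["calendar_week"].astype("Int64") == time_point]
    if sub.empty:
        raise DataError(f"no biological samples at calendar week {time_point}")
    group = sub["variety"].astype(str) + "/" + sub["cultivation"].astype(str)
    sizes = group.value_counts()
    small = sizes[sizes < min_replicates].index.tolist()
    if small:
        warnings.warn(f"excluding single-replicate group(s) at week {time_point}: {small}", stacklevel=2)
        keep = group.isin(sizes[sizes >= min_replicates].index)
        sub, group = sub[keep], group[keep]
    groups = sorted(group.unique())
    if len(groups) < 2:
        raise DataError(f"fewer than 2 variety x cultivation groups at week {time_point}")

    data = matrix.data.loc[sub["sample_id"]]
    gidx = group.map({g: i for i, g in enumerate(groups)}).to_numpy()
    G = len(groups)
    m = data.shape[1]
    Fs = np.full(m, np.nan)
    sigma2 = np.full(m, np.nan)
    dfr = np.zeros(m)
    amean = np.full(m, np.nan)
    fitted = np.zeros(m, dtype=bool)
    quad = np.full(m, np.nan)
    qs = np.full(m, np.nan)

    Y = data.to_numpy(dtype=float)
    for g in range(m):
        y = Y[:, g]
        obs = ~np.isnan(y)
        labs = gidx[obs]
        y = y[obs]
        present = np.unique(labs)
        n_obs, k = len(y), len(present)
        if k < 2 or n_obs - k < 1:
            continue
        means = np.array([y[labs == gg].mean() for gg in present])
        counts = np.array([(labs == gg).sum() for gg in present])
        grand = y.mean()
        ss_between = float((counts * (means - grand) ** 2).sum())
        ss_within = float(((y - means[np.searchsorted(present, labs)]) ** 2).sum())
        d = n_obs - k
        sigma2[g] = ss_within / d
        dfr[g] = d
        amean[g] = grand
        quad[g] = ss_between
        qs[g] = k - 1
        fitted[g] = True

    lite = FitResult(
        design=None,
        compounds=list(data.columns),
        coef=np.zeros((m, 1)),
        cov=np.zeros((m, 1, 1)),
        sigma2=sigma2,
        df_resid=dfr,
        amean=amean,
        fitted=fitted,
        partial=np.zeros(m, dtype=bool),
        dropped=[[] for _ in range(m)],
    )
    prior = estimate_prior(lite, span=span)
    s2_post = prior.posterior_var(sigma2, dfr)
    df2 = prior.total_df(dfr)
    from scipy import stats as sps

    pv = np.full(m, np.nan)
    for g in range(m):
        if fitted[g] and s2_post[g] > 0:
            Fs[g] = quad[g] / qs[g] / s2_post[g]
            pv[g] = sps.f.sf(Fs[g], qs[g], df2[g])
    out = pd.DataFrame(
        {
            "F": Fs,
            "p": pv,
            "adj_p": bh_adjust(pv),
            "n_groups": np.where(fitted, qs + 1, np.nan),
            "df_resid": dfr,
        },
        index=pd.Index(data.columns, name="compound_id"),
    )
    out.attrs["groups"] = groups
    out.attrs["calendar_week"] = int(time_point)
    return out
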