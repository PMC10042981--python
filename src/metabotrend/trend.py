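"""Per-compound spline time-trend models with empirical-Bayes moderation.

Each compound's log2 abundance is modelled over biological samples as

    y = beta_v + B_v(week) . (gamma + delta_v) + e,   e ~ N(0, sigma_g^2)

with one intercept per variety (its level at the anchored first harvest
week), a common 3-df natural-spline time trend ``gamma``, and sum-to-zero
per-variety spline deviations ``delta_v`` (so ``gamma`` is the across-variety
mean trend). The anchored basis makes the fitted time effect of variety v at
week w an exact log fold change from that variety's first sampled week.

Residual variances are shrunk towards a mean-dependent prior trend with the
classic empirical-Bayes scheme: the prior degrees of freedom ``d0`` are
obtained by matching the spread of log residual variances around the trend
to the theoretical scaled-F log-variance via trigamma inversion, and the
posterior variance is the ``d0``/``d_g``-weighted pool. Effects (Variety,
Time, Interaction) are tested with moderated F-statistics on
``F(q, d0 + d_g)`` and BH-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .datatypes import AbundanceMatrix, biological_mask
from .exceptions import DataError, ValidationError
from .splines import SplineBasis, natural_spline_basis

logger = logging.getLogger(__name__)

EFFECTS = ("Variety", "Time", "Interaction")

#: effective degrees of freedom used in place of an infinite prior df
D0_CAP = 1e7

__all__ = [
    "ModelDesign",
    "FitResult",
    "PriorEstimate",
    "build_design",
    "fit_ols",
    "estimate_prior",
    "moderated_f",
    "bh_adjust",
    "classify_effects",
    "predict_trends",
    "SplineTrendModel",
    "EFFECTS",
]


@dataclass
class ModelDesign:
    """Design matrix over biological samples plus its coefficient layout."""

    matrix: np.ndarray                 # n_samples x p
    sample_ids: list
    columns: list                      # coefficient labels
    varieties: list                    # variety names, design order; last is the
                                       # sum-to-zero reference
    spline_df: int
    bases: dict                        # variety -> SplineBasis (anchored, on its weeks)
    weeks: dict                        # variety -> sorted observed week indices

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def contrast(self, effect: str) -> np.ndarray | None:
        """Contrast matrix L (q x p) whose joint nullity defines ``effect``."""
        V, k = len(self.varieties), self.spline_df
        if effect == "Variety":
            if V < 2:
                return None
            L = np.zeros((V - 1, self.p))
            for i in range(V - 1):
                L[i, i] = 1.0
                L[i, V - 1] = -1.0
            return L
        if effect == "Time":
            L = np.zeros((k, self.p))
            L[:, V : V + k] = np.eye(k)
            return L
        if effect == "Interaction":
            if V < 2:
                return None
            q = k * (V - 1)
            L = np.zeros((q, self.p))
            L[:, V + k :] = np.eye(q)
            return L
        raise ValidationError(f"unknown effect {effect!r}; expected one of {EFFECTS}")

    def curve_functional(self, variety: str, weeks=None) -> tuple[np.ndarray, np.ndarray]:
        """Rows a_w with a_w . coef = modelled logFC of ``variety`` at week w."""
        V, k = len(self.varieties), self.spline_df
        j = self.varieties.index(variety)
        basis = self.bases[variety]
        if weeks is None:
            weeks = self.weeks[variety]
        weeks = np.asarray(weeks, dtype=float)
        B = basis.evaluate(weeks)  # anchored rows
        A = np.zeros((len(weeks), self.p))
        A[:, V : V + k] = B
        if V > 1:
            if j < V - 1:
                A[:, V + k + j * k : V + k + (j + 1) * k] = B
            else:  # sum-to-zero reference variety: delta_V = -sum(others)
                for i in range(V - 1):
                    A[:, V + k + i * k : V + k + (i + 1) * k] = -B
        return np.asarray(weeks), A


def build_design(
    samples: pd.DataFrame,
    varieties=None,
    df: int = 3,
    min_weeks: int = 6,
) -> ModelDesign:
    """Build the variety + spline-time + interaction design.

    Only varieties sampled in at least ``min_weeks`` distinct weeks spanning
    their first and final harvest week qualify (relax via ``min_weeks``).
    Each selected variety must map to a single cultivation series.
    """
    bio = samples[biological_mask(samples)].copy()
    if varieties is None:
        counts = bio.groupby("variety")["harvest_week_index"].nunique()
        varieties = sorted(counts[counts >= min_weeks].index)
    varieties = list(varieties)
    if not varieties:
        raise ValidationError("no varieties qualify for trend modelling")
    bio = bio[bio["variety"].isin(varieties)]
    for v in varieties:
        sub = bio[bio["variety"] == v]
        if sub.empty:
            raise ValidationError(f"variety {v!r} has no biological samples")
        if sub["cultivation"].nunique() > 1:
            raise ValidationError(
                f"variety {v!r} spans multiple cultivation series; filter the sample table "
                "to one series per variety before modelling"
            )
        wk = np.sort(sub["harvest_week_index"].astype(int).unique())
        if len(wk) < min_weeks:
            raise ValidationError(
                f"variety {v!r} has {len(wk)} harvest weeks; >= {min_weeks} required "
                "(lower min_weeks to override)"
            )

    V, k = len(varieties), df
    bases, weeks = {}, {}
    for v in varieties:
        wk = np.sort(bio.loc[bio["variety"] == v, "harvest_week_index"].astype(int).unique())
        weeks[v] = wk
        times = bio.loc[bio["variety"] == v, "harvest_week_index"].astype(float).to_numpy()
        bases[v] = natural_spline_basis(times, df=df, anchored=True)

    n = len(bio)
    p = V + k + (k * (V - 1) if V > 1 else 0)
    X = np.zeros((n, p))
    columns = [f"intercept:{v}" for v in varieties] + [f"time:{i + 1}" for i in range(k)]
    for v in varieties[:-1]:
        columns += [f"ixn:{v}:{i + 1}" for i in range(k)]

    var_idx = {v: i for i, v in enumerate(varieties)}
    for row_i, (_, row) in enumerate(bio.iterrows()):
        v = row["variety"]
        j = var_idx[v]
        X[row_i, j] = 1.0
        b = bases[v].evaluate([float(row["harvest_week_index"])])[0]
        X[row_i, V : V + k] = b
        if V > 1:
            if j < V - 1:
                X[row_i, V + k + j * k : V + k + (j + 1) * k] = b
            else:
                for i in range(V - 1):
                    X[row_i, V + k + i * k : V + k + (i + 1) * k] = -b

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, pivoting=True, mode="economic")
        aliased = [columns[i] for i in piv[rank:]]
        raise ValidationError(f"design is rank deficient; aliased columns: {aliased}")

    return ModelDesign(
        matrix=X,
        sample_ids=bio["sample_id"].tolist(),
        columns=columns,
        varieties=varieties,
        spline_df=k,
        bases=bases,
        weeks=weeks,
    )


@dataclass
class FitResult:
    """Per-compound least-squares results aligned to a :class:`ModelDesign`."""

    design: ModelDesign
    compounds: list
    coef: np.ndarray          # n_compounds x p (NaN where a column was dropped)
    cov: np.ndarray           # n_compounds x p x p unscaled (X'X)^-1 (NaN where dropped)
    sigma2: np.ndarray        # residual variances s_g^2
    df_resid: np.ndarray      # d_g
    amean: np.ndarray         # average observed log2 abundance A_g
    fitted: np.ndarray        # bool: enough observations to fit
    partial: np.ndarray       # bool: some columns dropped (variety unobserved)
    dropped: list = field(default_factory=list)  # per compound: list of dropped column idx


def fit_ols(matrix, design: ModelDesign) -> FitResult:
    """Ordinary least squares per compound on observed cells only.

    Compounds missing an entire variety get the aliased (all-zero) columns
    dropped and are flagged partial; compounds with fewer observations than
    the rank of their row-subset design are flagged unfitted.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    missing_ids = [s for s in design.sample_ids if s not in data.index]
    if missing_ids:
        raise DataError(f"design sample {missing_ids[0]!r} absent from matrix")
    Y = data.loc[design.sample_ids].to_numpy(dtype=float)
    X = design.matrix
    n, p = X.shape
    m = Y.shape[1]

    coef = np.full((m, p), np.nan)
    cov = np.full((m, p, p), np.nan)
    sigma2 = np.full(m, np.nan)
    df_resid = np.zeros(m)
    amean = np.full(m, np.nan)
    fitted = np.zeros(m, dtype=bool)
    partial = np.zeros(m, dtype=bool)
    dropped: list = [[] for _ in range(m)]

    obs = ~np.isnan(Y)
    # group compounds by missingness pattern so the common complete case is
    # solved once for all compounds sharing it
    patterns: dict[bytes, list[int]] = {}
    for g in range(m):
        patterns.setdefault(obs[:, g].tobytes(), []).append(g)

    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n_obs = int(mask.sum())
        Xs = X[mask]
        candidates = np.nonzero(~np.all(Xs == 0.0, axis=0))[0]
        if len(candidates) == p and np.linalg.matrix_rank(Xs) == p:
            keep_cols = list(range(p))
        else:
            # greedy full-rank column subset in design order, so intercepts and
            # the common trend survive when interaction columns become aliased
            keep_cols = []
            for c in candidates:
                trial = Xs[:, keep_cols + [int(c)]]
                if np.linalg.matrix_rank(trial) > len(keep_cols):
                    keep_cols.append(int(c))
        keep = np.zeros(p, dtype=bool)
        keep[keep_cols] = True
        Xk = Xs[:, keep]
        rank = len(keep_cols)
        if rank == 0 or n_obs <= rank:
            # unidentifiable or saturated for this pattern
            for g in idx:
                amean[g] = np.nanmean(Y[:, g]) if mask.any() else np.nan
            logger.info("flagging %d compound(s) unfitted (n_obs=%d, rank=%d)", len(idx), n_obs, rank)
            continue
        XtX_inv = np.linalg.inv(Xk.T @ Xk)
        proj = XtX_inv @ Xk.T
        Ys = Y[np.ix_(mask, idx)]
        B = proj @ Ys                      # p_k x len(idx)
        resid = Ys - Xk @ B
        rss = (resid**2).sum(axis=0)
        d = n_obs - rank
        keep_idx = np.nonzero(keep)[0]
        for j, g in enumerate(idx):
            coef[g, keep_idx] = B[:, j]
            cov[g][np.ix_(keep_idx, keep_idx)] = XtX_inv
            sigma2[g] = rss[j] / d
            df_resid[g] = d
            amean[g] = Ys[:, j].mean()
            fitted[g] = True
            if not keep.all():
                partial[g] = True
                dropped[g] = [int(c) for c in np.nonzero(~keep)[0]]

    compounds = list(data.columns)
    return FitResult(
        design=design,
        compounds=compounds,
        coef=coef,
        cov=cov,
        sigma2=sigma2,
        df_resid=df_resid,
        amean=amean,
        fitted=fitted,
        partial=partial,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _tricube_local_linear(x: np.ndarray, y: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Locally weighted linear smoother (tricube kernel, nearest-neighbour span)."""
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            out[i] = ys[d == 0].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        slope = (w * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (xs[i] - xm)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class PriorEstimate:
    """Empirical-Bayes prior: global df ``d0`` and per-compound ``s0_g^2``."""

    d0: float | np.ndarray
    s02: np.ndarray

    def posterior_var(self, sigma2: np.ndarray, df_resid: np.ndarray) -> np.ndarray:
        """Pooled posterior variance s~_g^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
        s2 = np.asarray(sigma2, dtype=float)
        d = np.asarray(df_resid, dtype=float)
        d0 = np.broadcast_to(np.asarray(self.d0, dtype=float), s2.shape)
        s02 = np.broadcast_to(np.asarray(self.s02, dtype=float), s2.shape)
        finite = np.isfinite(d0)
        d0f = np.where(finite, d0, 0.0)
        pooled = (d0f * s02 + d * s2) / (d0f + d)
        return np.where(finite, pooled, s02)

    def total_df(self, df_resid) -> np.ndarray:
        d = np.asarray(df_resid, dtype=float)
        d0 = np.broadcast_to(np.asarray(self.d0, dtype=float), d.shape)
        return np.minimum(d0 + d, D0_CAP)


def estimate_prior(fit: FitResult, span: float = 0.5, min_compounds: int = 30) -> PriorEstimate:
    """Estimate (d0, s0_g^2) from the ensemble of residual variances.

    The log residual variances are detrended against average abundance with
    a locally weighted linear smoother (the mean-variance trend); the excess
    spread of the detrended values over the sampling spread trigamma(d_g/2)
    determines ``d0`` by trigamma inversion. If the empirical spread does
    not exceed the theoretical one, ``d0`` is infinite (full shrinkage to
    the trend).
    """
    ok = fit.fitted & (fit.df_resid >= 1) & (fit.sigma2 > 0)
    m_all = len(fit.sigma2)
    s02 = np.full(m_all, np.nan)
    if ok.sum() < 2:
        raise DataError("too few fitted compounds to estimate a variance prior")

    s2 = fit.sigma2[ok]
    d = fit.df_resid[ok]
    A = fit.amean[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)

    if ok.sum() < min_compounds or np.ptp(A) == 0:
        logger.info("estimate_prior: %d compounds < %d; using a constant variance trend", int(ok.sum()), min_compounds)
        e0 = np.full(len(e), e.mean())
    else:
        e0 = _tricube_local_linear(A, e, span=span)

    resid = e - e0
    n = len(resid)
    evar = resid.var(ddof=1) * n / max(n - 1, 1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
    else:
        d0 = np.inf
    if np.isinf(d0):
        log_s02 = e0
    else:
        log_s02 = e0 + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    s02[ok] = np.exp(log_s02)
    # unfitted compounds keep NaN prior variances
    return PriorEstimate(d0=float(d0), s02=s02)


def moderated_f(fit: FitResult, prior: PriorEstimate, effect: str):
    """Moderated F and p-value per compound for one effect.

    F = [ (L beta)' (L C L')^-1 (L beta) / q ] / s~^2 with q contrasts,
    referred to F(q, d0 + d_g). Compounds whose fit dropped a column used by
    the contrast (variety never observed) get NaN and are excluded from FDR.
    """
    L = fit.design.contrast(effect)
    m = len(fit.compounds)
    F = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    if L is None:
        return F, pval
    q = L.shape[0]
    s2_post = prior.posterior_var(fit.sigma2, fit.df_resid)
    df2 = prior.total_df(fit.df_resid)
    used = np.nonzero(np.any(L != 0.0, axis=0))[0]
    for g in range(m):
        if not fit.fitted[g]:
            continue
        if fit.dropped[g] and set(fit.dropped[g]) & set(used.tolist()):
            continue
        beta = fit.coef[g, used]
        C = fit.cov[g][np.ix_(used, used)]
        Lu = L[:, used]
        lb = Lu @ beta
        M = Lu @ C @ Lu.T
        try:
            quad = float(lb @ np.linalg.solve(M, lb))
        except np.linalg.LinAlgError:
            continue
        F[g] = quad / q / s2_post[g]
        pval[g] = stats.f.sf(F[g], q, df2[g])
    return F, pval


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    ps = p[ok]
    n = len(ps)
    if n == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


def classify_effects(stats_df: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Assign each compound to one of the 8 effect classes.

    ``stats_df`` must carry columns ``adj_p_Variety``, ``adj_p_Time``,
    ``adj_p_Interaction`` indexed by compound. The label joins the
    significant effects with '+'; compounds significant nowhere are 'none';
    compounds with no testable effect are 'unfitted'.
    """
    labels = []
    for _, row in stats_df.iterrows():
        sig = [
            eff
            for eff in EFFECTS
            if not np.isnan(row[f"adj_p_{eff}"]) and row[f"adj_p_{eff}"] < alpha
        ]
        if all(np.isnan(row[f"adj_p_{eff}"]) for eff in EFFECTS):
            labels.append("unfitted")
        elif sig:
            labels.append("+".join(sig))
        else:
            labels.append("none")
    return pd.Series(labels, index=stats_df.index, name="effect_class")


def predict_trends(
    fit: FitResult,
    prior: PriorEstimate,
    weeks: dict | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Modelled weekly logFC curves with pointwise confidence intervals.

    Returns a long table (compound, variety, week, logfc, se, ci_lo, ci_hi).
    Week 1 is the anchored reference: its logFC and CI half-width are
    exactly 0.
    """
    design = fit.design
    s2_post = prior.posterior_var(fit.sigma2, fit.df_resid)
    df2 = prior.total_df(fit.df_resid)
    rows = []
    for v in design.varieties:
        wk, A = design.curve_functional(v, None if weeks is None else weeks.get(v))
        used = np.nonzero(np.any(A != 0.0, axis=0))[0]
        for g, comp in enumerate(fit.compounds):
            if not fit.fitted[g]:
                continue
            if fit.dropped[g] and set(fit.dropped[g]) & set(used.tolist()):
                continue
            est = A @ np.nan_to_num(fit.coef[g])
            C = np.nan_to_num(fit.cov[g])
            var = np.einsum("wp,pq,wq->w", A, C, A) * s2_post[g]
            se = np.sqrt(np.clip(var, 0, None))
            tq = stats.t.ppf(0.5 + level / 2.0, df2[g])
            for wi, w in enumerate(wk):
                rows.append(
                    (comp, v, int(w), est[wi], se[wi], est[wi] - tq * se[wi], est[wi] + tq * se[wi])
                )
    return pd.DataFrame(
        rows, columns=["compound_id", "variety", "week", "logfc", "se", "ci_lo", "ci_hi"]
    )


class SplineTrendModel(BaseEstimator):
    """Sklearn-style front end: fit all per-compound trend models at once.

    Parameters
    ----------
    df : spline degrees of freedom for the time trend (3 by default).
    alpha : BH-adjusted significance threshold for effect classes.
    min_weeks : minimum distinct harvest weeks per modelled variety.
    varieties : explicit variety subset, or None to auto-select those with
        >= min_weeks weeks.
    span : span of the mean-variance trend smoother.
    platform_split : moderate variances separately per platform (requires a
        compound table with a ``platform`` column at fit time).

    Attributes (after fit)
    ----------------------
    design_, fit_, prior_ : the model internals.
    stats_ : DataFrame with F/p/adjusted p per effect, indexed by compound.
    classes_ : per-compound effect class labels.
    """

    def __init__(
        self,
        df: int = 3,
        alpha: float = 0.05,
        min_weeks: int = 6,
        varieties=None,
        span: float = 0.5,
        platform_split: bool = False,
    ):
        self.df = df
        self.alpha = alpha
        self.min_weeks = min_weeks
        self.varieties = varieties
        self.span = span
        self.platform_split = platform_split

    def fit(self, X, samples: pd.DataFrame, compounds: pd.DataFrame | None = None):
        data = X.data if isinstance(X, AbundanceMatrix) else X
        design = build_design(
            samples, varieties=self.varieties, df=self.df, min_weeks=self.min_weeks
        )
        fit = fit_ols(data, design)

        if self.platform_split:
            if compounds is None or "platform" not in compounds.columns:
                raise ValidationError("platform_split requires a compound table with a platform column")
            platform = compounds.set_index("compound_id").loc[fit.compounds, "platform"].to_numpy()
            # moderate each platform against its own ensemble, then merge the
            # per-platform priors into one per-compound prior
            d0 = np.full(len(fit.compounds), np.nan)
            s02 = np.full(len(fit.compounds), np.nan)
            priors = {}
            for plat in pd.unique(platform):
                sub_idx = platform == plat
                pr = estimate_prior(_subset_fit(fit, sub_idx), span=self.span)
                priors[plat] = pr
                d0[sub_idx] = pr.d0
                s02[sub_idx] = pr.s02
            self.platform_priors_ = priors
            prior = PriorEstimate(d0=d0, s02=s02)
        else:
            self.platform_priors_ = None
            prior = estimate_prior(fit, span=self.span)

        stats_df = pd.DataFrame(index=pd.Index(fit.compounds, name="compound_id"))
        for eff in EFFECTS:
            F, pv = moderated_f(fit, prior, eff)
            stats_df[f"F_{eff}"] = F
            stats_df[f"p_{eff}"] = pv
            stats_df[f"adj_p_{eff}"] = bh_adjust(pv)

        self.design_ = design
        self.fit_ = fit
        self.prior_ = prior
        self.stats_ = stats_df
        self.classes_ = classify_effects(stats_df, alpha=self.alpha)
        return self

    def predict_trends(self, weeks: dict | None = None, level: float = 0.95) -> pd.DataFrame:
        return predict_trends(self.fit_, self.prior_, weeks=weeks, level=level)

    @property
    def changing_compounds_(self) -> list:
        """Compounds changing over time for at least one variety (Time u Interaction)."""
        sig = self.stats_
        mask = (sig["adj_p_Time"] < self.alpha) | (sig["adj_p_Interaction"] < self.alpha)
        return sig.index[mask.fillna(False)].tolist()


def _subset_fit(fit: FitResult, idx: np.ndarray) -> FitResult:
    return FitResult(
        design=fit.design,
        compounds=[c for c, k in zip(fit.compounds, idx) if k],
        coef=fit.coef[idx],
        cov=fit.cov[idx],
        sigma2=fit.sigma2[idx],
        df_resid=fit.df_resid[idx],
        amean=fit.amean[idx],
        fitted=fit.fitted[idx],
        partial=fit.partial[idx],
        dropped=[d for d, k in zip(fit.dropped, idx) if k],
    )
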