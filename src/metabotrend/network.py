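"""Signed weighted-correlation network clustering of modelled time-trends.

Compounds whose modelled trends (concatenated across varieties) are highly
positively correlated are grouped into modules: the signed adjacency
``a_ij = ((1 + cor)/2)^beta`` suppresses anticorrelated pairs, the
topological overlap measure (TOM) reinforces pairs that share network
neighbourhoods, and modules are branches of an average-linkage tree on
``1 - TOM`` that survive a minimum-size adaptive cut, a kME membership
filter, and an eigengene-similarity merge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import DataError, ValidationError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: deepSplit 0..4 mapped to the fraction of a (sub)tree's height at which it
#: is re-cut while searching for branches. A higher fraction probes closer to
#: each branch top and therefore splits more aggressively; 0.85 (deepSplit 2)
#: is the default operating point.
DEEP_SPLIT_HEIGHT_FRACTION = {0: 0.60, 1: 0.75, 2: 0.85, 3: 0.92, 4: 0.98}

__all__ = [
    "concatenate_trends",
    "signed_adjacency",
    "tom_similarity",
    "cluster_tree",
    "dynamic_cut",
    "module_eigengene",
    "kme_prune_and_merge",
    "TOMModuleClustering",
    "ModuleAssignment",
    "linkage_to_newick",
    "UNASSIGNED",
]


def concatenate_trends(curves: pd.DataFrame, compounds=None) -> pd.DataFrame:
    """Pivot long-format trend curves to a compounds x (variety, week) matrix.

    ``curves`` is the long table produced by the trend model (columns
    compound_id, variety, week, logfc). ``compounds`` restricts the rows
    (typically the Time-or-Interaction significant set). Column order is
    variety blocks in sorted order, weeks ascending; every block starts at
    the anchored zero week.
    """
    sel = curves if compounds is None else curves[curves["compound_id"].isin(set(compounds))]
    if compounds is not None:
        missing = set(compounds) - set(sel["compound_id"])
        if missing:
            raise DataError(f"no trend curve for compound {sorted(missing)[0]!r}")
    if sel.empty:
        raise DataError("nothing to cluster: the selected compound set is empty")
    wide = sel.pivot_table(
        index="compound_id", columns=["variety", "week"], values="logfc", sort=True
    )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise DataError(f"compound {bad!r} is missing part of its concatenated trend")
    if compounds is not None:
        wide = wide.loc[[c for c in compounds if c in wide.index]]
    return wide


def signed_adjacency(trends: pd.DataFrame | np.ndarray, beta: float = 12) -> np.ndarray:
    """Signed soft-thresholded adjacency a_ij = ((1 + cor_ij)/2)^beta."""
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    X = trends.to_numpy(dtype=float) if isinstance(trends, pd.DataFrame) else np.asarray(trends, dtype=float)
    if X.shape[1] < 3:
        raise ValidationError("need >= 3 profile columns to correlate trends")
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValidationError(
            f"{int((sd == 0).sum())} zero-variance profile(s); exclude them before clustering"
        )
    r = np.corrcoef(X)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), the sum
    excluding u in {i, j} and k the connectivity sum_{u != i} a_iu;
    TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.nanmin(a) < -1e-12 or np.nanmax(a) > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a  # includes u == i and u == j terms, removed below
    num = shared - np.diag(a)[:, None] * a - a * np.diag(a)[None, :] + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def cluster_tree(diss: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical tree on a dissimilarity matrix.

    Returns a scipy linkage matrix; merge heights are non-decreasing for
    average linkage, and tie handling is deterministic.
    """
    d = np.asarray(diss, dtype=float)
    if d.shape[0] < 2:
        raise ValidationError("need at least 2 items to build a tree")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return average(squareform(d, checks=False))


def dynamic_cut(
    linkage: np.ndarray,
    diss: np.ndarray | None = None,
    min_module_size: int = 10,
    deep_split: int = 2,
) -> np.ndarray:
    """Adaptive tree cut into provisional modules.

    The tree is cut at ``frac(deep_split) * top height``; each resulting
    branch with >= ``min_module_size`` leaves is then recursively re-cut at
    the same fraction of its own internal height. Leaves on no qualifying
    branch are then assigned PAM-style to the nearest module (by average
    dissimilarity) when they are closer to it than to the network at large
    (requires ``diss``); the rest stay 0 (unassigned). Returns integer
    labels (1..k in decreasing size order, 0 = unassigned).
    """
    if deep_split not in DEEP_SPLIT_HEIGHT_FRACTION:
        raise ValidationError(f"deep_split must be in 0..4, got {deep_split}")
    frac = DEEP_SPLIT_HEIGHT_FRACTION[deep_split]
    n = linkage.shape[0] + 1
    if min_module_size > n:
        warnings.warn("min_module_size exceeds the number of items; all unassigned", stacklevel=2)
        return np.zeros(n, dtype=int)
    root = to_tree(linkage)

    clusters: list[list[int]] = []

    def branches_below(node, cut_height):
        """Maximal subtrees whose merge height is below cut_height."""
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd.dist <= cut_height or nd.is_leaf():
                out.append(nd)
            else:
                stack.extend([nd.left, nd.right])
        return out

    def recurse(node):
        height = node.dist
        if node.count < 2 * min_module_size or height == 0:
            clusters.append(node.pre_order())
            return
        cut = frac * height
        parts = branches_below(node, cut)
        big = [p for p in parts if p.count >= min_module_size]
        if not big:
            # nothing below the cut is large enough: keep the branch whole
            clusters.append(node.pre_order())
            return
        for p in big:
            recurse(p)
        # leaves of small off-branches stay unassigned

    if root.count >= min_module_size:
        recurse(root)

    labels = np.zeros(n, dtype=int)
    kept = [c for c in clusters if len(c) >= min_module_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    for i, c in enumerate(kept, start=1):
        labels[c] = i

    if diss is not None and kept:
        d = np.asarray(diss, dtype=float)
        others = np.arange(n)
        for i in np.nonzero(labels == 0)[0]:
            ambient = d[i, others != i].mean()
            cand = {
                m: d[i, labels == m].mean() for m in range(1, len(kept) + 1)
            }
            best = min(cand, key=lambda m: (cand[m], m))
            if cand[best] < ambient:
                labels[i] = best
    return labels


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengene(trends: np.ndarray, member_idx) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized profiles.

    Returns ``(eigengene, explained_variance_fraction)``; the eigengene is
    sign-aligned so its correlation with the module mean profile is
    positive. A singleton module's standardized profile is its eigengene.
    """
    member_idx = np.asarray(list(member_idx), dtype=int)
    Xs = _standardize_rows(np.asarray(trends, dtype=float)[member_idx])
    if len(member_idx) == 1:
        logger.info("singleton module: profile used as eigengene")
        return Xs[0], 1.0
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = Vt[0]
    explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = Xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig, explained


def _kme(profile: np.ndarray, eigengene: np.ndarray) -> float:
    p = profile - profile.mean()
    e = eigengene - eigengene.mean()
    den = np.sqrt((p**2).sum() * (e**2).sum())
    return float(p @ e / den) if den > 0 else 0.0


@dataclass
class ModuleAssignment:
    """Final module labels, module eigengenes and membership strengths."""

    labels: pd.Series            # compound -> "C1".."Ck" or "unassigned"
    kme: pd.Series               # cor(profile, own module eigengene); NaN if unassigned
    eigengenes: pd.DataFrame     # modules x concatenated-profile positions
    explained: pd.Series         # eigengene explained-variance fraction per module
    unassigned_reason: pd.Series  # "", "tree_cut", "kme_pruned", "module_dissolved"
    n_iterations: int = 0
    converged: bool = True


def kme_prune_and_merge(
    trends: pd.DataFrame,
    labels: np.ndarray,
    min_kme: float = 0.5,
    merge_cut_height: float = 0.25,
    min_module_size: int = 10,
    max_iter: int = 20,
) -> ModuleAssignment:
    """Iteratively prune weak members and merge similar modules.

    Each round (i) removes members whose correlation with their own module
    eigengene falls below ``min_kme``, (ii) merges the closest module pair
    with eigengene dissimilarity ``1 - cor`` below ``merge_cut_height``,
    recomputing eigengenes after every change, until a fixed point (or
    ``max_iter`` rounds, returned with a warning). Modules falling below
    ``min_module_size`` are dissolved. Final labels are C1..Ck by
    decreasing size.
    """
    X = trends.to_numpy(dtype=float)
    compounds = trends.index
    lab = np.asarray(labels, dtype=int).copy()
    reason = np.where(lab == 0, "tree_cut", "")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        changed = False
        eigs = {
            m: module_eigengene(X, np.nonzero(lab == m)[0])[0]
            for m in np.unique(lab) if m != 0
        }
        if not eigs:
            break
        # (i) kME pruning
        for m, eig in list(eigs.items()):
            members = np.nonzero(lab == m)[0]
            kmes = np.array([_kme(X[i], eig) for i in members])
            weak = members[kmes < min_kme]
            if len(weak):
                lab[weak] = 0
                reason[weak] = "kme_pruned"
                changed = True
        # dissolve undersized modules
        for m in list(np.unique(lab)):
            if m == 0:
                continue
            members = np.nonzero(lab == m)[0]
            if len(members) < min_module_size:
                lab[members] = 0
                reason[members] = "module_dissolved"
                changed = True
        eigs = {
            m: module_eigengene(X, np.nonzero(lab == m)[0])[0]
            for m in np.unique(lab) if m != 0
        }
        # (ii) merge the closest pair below the cut height
        mods = sorted(eigs)
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                dis = 1.0 - _kme(eigs[mods[i]], eigs[mods[j]])
                if dis < merge_cut_height and (best is None or dis < best[0]):
                    best = (dis, mods[i], mods[j])
        if best is not None:
            _, mi, mj = best
            lab[lab == mj] = mi
            changed = True
        if not changed:
            converged = True
            break
    if not converged and it == max_iter:
        warnings.warn(f"module prune/merge did not converge in {max_iter} iterations", stacklevel=2)

    # relabel C1..Ck by decreasing size (ties by smallest member index)
    mods = [m for m in np.unique(lab) if m != 0]
    sizes = {m: int((lab == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], int(np.nonzero(lab == m)[0][0])))
    name_of = {m: f"C{i + 1}" for i, m in enumerate(order)}

    final_labels = pd.Series(
        [name_of.get(v, UNASSIGNED) for v in lab], index=compounds, name="module"
    )
    kme_vals = np.full(len(lab), np.nan)
    eig_rows, expl = {}, {}
    for m in order:
        idx = np.nonzero(lab == m)[0]
        eig, ev = module_eigengene(X, idx)
        eig_rows[name_of[m]] = eig
        expl[name_of[m]] = ev
        for i in idx:
            kme_vals[i] = _kme(X[i], eig)
    eigengenes = pd.DataFrame.from_dict(eig_rows, orient="index")
    if isinstance(trends.columns, pd.MultiIndex) and len(eigengenes):
        eigengenes.columns = trends.columns
    return ModuleAssignment(
        labels=final_labels,
        kme=pd.Series(kme_vals, index=compounds, name="kME"),
        eigengenes=eigengenes,
        explained=pd.Series(expl, name="explained_variance"),
        unassigned_reason=pd.Series(reason, index=compounds, name="unassigned_reason"),
        n_iterations=it,
        converged=converged,
    )


class TOMModuleClustering(ClusterMixin, BaseEstimator):
    """Full signed-WCNA module detection over a trend matrix.

    Parameters follow the field's conventional names: soft-threshold
    ``beta`` (12), ``min_module_size`` (10), ``deep_split`` (2),
    ``min_kme`` (0.5) and ``merge_cut_height`` (0.25).

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of module names ("C1".. or "unassigned") per row.
    assignment_ : the full :class:`ModuleAssignment`.
    adjacency_, tom_ : the intermediate matrices.
    linkage_ : scipy linkage matrix of the average-linkage tree on 1 - TOM.
    """

    def __init__(
        self,
        beta: float = 12,
        min_module_size: int = 10,
        deep_split: int = 2,
        min_kme: float = 0.5,
        merge_cut_height: float = 0.25,
    ):
        self.beta = beta
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.min_kme = min_kme
        self.merge_cut_height = merge_cut_height

    def fit(self, X: pd.DataFrame, y=None):
        trends = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.adjacency_ = signed_adjacency(trends, beta=self.beta)
        self.tom_ = tom_similarity(self.adjacency_)
        diss = 1.0 - self.tom_
        self.linkage_ = cluster_tree(diss)
        provisional = dynamic_cut(
            self.linkage_,
            diss,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
        )
        self.assignment_ = kme_prune_and_merge(
            trends,
            provisional,
            min_kme=self.min_kme,
            merge_cut_height=self.merge_cut_height,
            min_module_size=self.min_module_size,
        )
        self.labels_ = self.assignment_.labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def linkage_to_newick(linkage: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage tree to a Newick string with branch lengths."""
    tree = to_tree(linkage)
    names = list(leaf_names)

    def build(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return build(tree, tree.dist) + ";"


def hub_order(linkage: np.ndarray) -> np.ndarray:
    """Deterministic leaf order of the dendrogram."""
    return leaves_list(linkage)
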