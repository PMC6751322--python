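"""Signed weighted co-expression network construction and module detection.

Given a subjects x metabolites matrix of log2 change scores, the network
stage builds a signed weighted adjacency ``a_ij = ((1 + r_ij)/2)^beta`` from
pairwise Pearson correlations, converts it to the topological overlap
measure (TOM), clusters metabolites on the 1-TOM dissimilarity with average
linkage and a dynamic hybrid tree cut, summarizes each module by its
eigenvector (first principal component of the standardized member changes
across subjects), and greedily merges modules whose eigenvectors correlate
above a threshold. Defaults are beta=18, deep_split=2, min_size=3, and a
merge threshold of 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from metacoex.types import DataError

DEFAULT_BETA = 18
DEFAULT_DEEP_SPLIT = 2
DEFAULT_MIN_SIZE = 3
DEFAULT_MERGE_THRESHOLD = 0.75

UNASSIGNED = "grey"

# Conventional module color sequence (grey reserved for unassigned).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

# deep_split 0..4 -> fraction of the joining-height range at which the
# dendrogram is cut; higher deep_split cuts lower and splits more aggressively
_DEEP_SPLIT_CUT_FRACTION = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.80, 4: 0.75}


@dataclass
class ModulePartition:
    """Final module assignment with eigenvectors, hubs, and merge history."""

    labels: pd.Series  # metabolite_id -> module name; UNASSIGNED for grey
    eigenvectors: pd.DataFrame  # subjects x modules, unit-norm columns
    explained_variance: dict  # module -> fraction of member variance
    hubs: dict = field(default_factory=dict)  # module -> metabolite_id
    merge_history: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def modules(self) -> list:
        return list(self.eigenvectors.columns)

    def members(self, module) -> list:
        return sorted(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)


def _correlations(changes: pd.DataFrame) -> np.ndarray:
    X = changes.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise DataError("need at least 3 subjects to estimate correlations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = changes.columns[np.where(sd == 0)[0][0]]
        raise DataError(f"constant change vector for metabolite {bad!r}")
    r = np.corrcoef(X, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(changes: pd.DataFrame, beta: int = DEFAULT_BETA) -> pd.DataFrame:
    """Signed weighted adjacency ``((1 + r)/2)^beta`` with unit diagonal."""
    if beta < 1 or int(beta) != beta:
        raise DataError("beta must be a positive integer")
    r = _correlations(changes)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=changes.columns, columns=changes.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins log10(k) into equal-occupancy bins, regresses log10 frequency
    density on log10 mean connectivity, and returns (signed R^2, mean k);
    the fit index is negated when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise DataError("all connectivities identical: scale-free fit undefined")
    order = np.sort(k)
    xs, ys = [], []
    for chunk in np.array_split(order, n_bins):
        if len(chunk) == 0:
            continue
        width = chunk.max() - chunk.min()
        if width <= 0 or chunk.mean() <= 0:
            continue
        density = len(chunk) / (len(k) * width)
        xs.append(np.log10(chunk.mean()))
        ys.append(np.log10(density))
    if len(xs) < 3:
        raise DataError("too few informative bins for a scale-free fit")
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    signed = -r2 if fit.slope > 0 else r2
    return float(signed), float(k.mean())


def pick_soft_threshold(
    changes: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    fit_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft threshold by the scale-free topology criterion.

    Returns the smallest candidate beta whose signed fit index reaches
    ``fit_target`` together with the full fit table; if no candidate
    qualifies, returns the conventional signed-network default (18) with a
    warning.
    """
    if not len(candidate_betas):
        raise DataError("candidate_betas must be nonempty")
    rows = []
    for beta in candidate_betas:
        adj = signed_adjacency(changes, beta).to_numpy()
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        fit, mean_k = _scale_free_fit(k)
        rows.append({"beta": int(beta), "fit": fit, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= fit_target]
    if len(ok):
        return int(ok["beta"].iloc[0]), table
    warnings.warn(
        f"no candidate beta reached fit target {fit_target}; "
        f"falling back to default beta={DEFAULT_BETA}",
        stacklevel=2,
    )
    return DEFAULT_BETA, table


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap measure of a weighted adjacency.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivities ``k_i = sum_{u != i} a_iu``; the diagonal is 1.
    """
    A = adj.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise DataError("adjacency must be square and symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise DataError("adjacency entries must lie in [0, 1]")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    shared = A0 @ A0  # (i,j) entry already excludes u=i and u=j
    numer = shared + A0
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cut_tree_dynamic(
    dissimilarity: pd.DataFrame,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.Series:
    """Dynamic hybrid cut of the average-linkage tree on a dissimilarity.

    Two stages: (1) the dendrogram is cut at a deep_split-dependent fraction
    of its joining-height range and clusters of at least ``min_size`` leaves
    become cores; (2) each remaining leaf joins the core with the smallest
    mean dissimilarity, provided that distance stays below the cut height.
    Leaves assigned to no core are labeled 0 (unassigned / grey).
    """
    if deep_split not in _DEEP_SPLIT_CUT_FRACTION:
        raise DataError("deep_split must be in {0, 1, 2, 3, 4}")
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise DataError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise DataError("dissimilarity diagonal must be zero")
    n = D.shape[0]
    if n < 2:
        return pd.Series(np.zeros(n, dtype=int), index=dissimilarity.index)
    Ds = (D + D.T) / 2.0
    np.fill_diagonal(Ds, 0.0)
    Z = hierarchy.linkage(squareform(Ds, checks=False), method="average")
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    frac = _DEEP_SPLIT_CUT_FRACTION[deep_split]
    cut_height = hmin + frac * (hmax - hmin)

    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    next_label = 1
    core_ids = []
    for cid in np.unique(flat):
        members = np.where(flat == cid)[0]
        if len(members) >= min_size:
            labels[members] = next_label
            core_ids.append(next_label)
            next_label += 1

    if core_ids:
        # hybrid stage: adopt stragglers that sit closer than the cut height
        unassigned = np.where(labels == 0)[0]
        for i in unassigned:
            dists = [
                (Ds[i, labels == c].mean(), c) for c in core_ids
            ]
            best_dist, best_c = min(dists)
            if best_dist < cut_height:
                labels[i] = best_c
    return pd.Series(labels, index=dissimilarity.index, name="module")


def _standardize(X: np.ndarray, columns) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = columns[np.where(sd == 0)[0][0]]
        raise DataError(f"constant member metabolite {bad!r} in module")
    return (X - mean) / sd


def module_eigenvector(
    changes: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Eigenvector (first PC across subjects) of each non-grey module.

    Member change vectors are column-standardized; the module eigenvector is
    the first left singular vector, unit norm, with its sign flipped so that
    it correlates nonnegatively with the module's mean standardized profile.
    Returns (subjects x modules eigenvector matrix, explained-variance map).
    """
    eig = {}
    explained = {}
    for module in _module_ids(labels):
        members = labels.index[labels == module]
        if len(members) < 2:
            raise DataError(f"module {module!r} has fewer than 2 members")
        X = _standardize(changes[members].to_numpy(dtype=float), list(members))
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        e = U[:, 0]
        profile = X.mean(axis=1)
        align = float(e @ profile)
        if align < 0 or (align == 0 and e[np.nonzero(e)[0][0]] < 0):
            e = -e
        eig[module] = e
        explained[module] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(eig, index=changes.index)
    return frame, explained


def _module_ids(labels: pd.Series) -> list:
    ids = [m for m in pd.unique(labels) if m != 0 and m != UNASSIGNED]
    return sorted(ids, key=lambda x: str(x))


def merge_modules(
    labels: pd.Series,
    changes: pd.DataFrame,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> ModulePartition:
    """Greedily merge modules whose eigenvectors correlate above threshold.

    Repeatedly merges the pair of modules with the highest eigenvector
    correlation while it exceeds ``merge_threshold``, recomputing
    eigenvectors after each merge. The terminal partition has no pair of
    module eigenvectors correlated above the threshold.
    """
    labels = labels.copy()
    history = []
    while True:
        modules = _module_ids(labels)
        if len(modules) < 2:
            break
        eig, _ = module_eigenvector(changes, labels)
        E = eig[modules].to_numpy()
        C = np.corrcoef(E, rowvar=False)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= merge_threshold:
            break
        keep, drop = sorted([modules[i], modules[j]], key=lambda x: str(x))
        history.append(
            {"merged": str(drop), "into": str(keep), "eigenvector_corr": float(C[i, j])}
        )
        labels[labels == drop] = keep
    eig, explained = module_eigenvector(changes, labels)
    return ModulePartition(
        labels=labels,
        eigenvectors=eig,
        explained_variance=explained,
        merge_history=history,
        params={"merge_threshold": merge_threshold},
    )


def hub_metabolites(adj: pd.DataFrame, partition: ModulePartition) -> dict:
    """Hub per module: member with maximal intramodular connectivity.

    ``kWithin_i = sum_{j in module, j != i} a_ij``; ties break toward the
    lexicographically smaller metabolite ID. Also stored on the partition.
    """
    hubs = {}
    for module in partition.modules:
        members = partition.members(module)
        sub = adj.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        kwithin = pd.Series(sub.sum(axis=1), index=members)
        best = kwithin[kwithin == kwithin.max()].index.min()
        hubs[module] = best
    partition.hubs = hubs
    return hubs


def intramodular_connectivity(adj: pd.DataFrame, partition: ModulePartition) -> pd.Series:
    """kWithin for every assigned metabolite (0 for grey)."""
    k = pd.Series(0.0, index=partition.labels.index, name="kWithin")
    for module in partition.modules:
        members = partition.members(module)
        sub = adj.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        k[members] = sub.sum(axis=1)
    return k


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Rename modules to conventional colors by decreasing size.

    Equal sizes break toward the module containing the smallest metabolite
    ID; overflow beyond the color list falls back to ``module_N``. The grey
    label is reserved for unassigned metabolites.
    """
    assigned = partition.labels[
        (partition.labels != 0) & (partition.labels != UNASSIGNED)
    ]
    sizes = assigned.value_counts()
    order = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], min(str(x) for x in partition.labels.index[partition.labels == m])),
    )
    mapping = {}
    for rank, module in enumerate(order):
        if rank < len(MODULE_COLORS):
            mapping[module] = MODULE_COLORS[rank]
        else:
            mapping[module] = f"module_{rank + 1}"
    new_labels = partition.labels.map(lambda m: mapping.get(m, UNASSIGNED))
    new_eig = partition.eigenvectors.rename(columns=mapping)
    new_eig = new_eig[[mapping[m] for m in order]]
    return ModulePartition(
        labels=new_labels,
        eigenvectors=new_eig,
        explained_variance={mapping[k]: v for k, v in partition.explained_variance.items()},
        hubs={mapping[k]: v for k, v in partition.hubs.items()},
        merge_history=partition.merge_history,
        params=partition.params,
    )


def detect_modules(
    changes: pd.DataFrame,
    beta: int = DEFAULT_BETA,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> tuple[ModulePartition, pd.DataFrame, pd.DataFrame]:
    """Full network stage: adjacency -> TOM -> cut -> merge -> colors -> hubs.

    Returns (partition, adjacency, TOM).
    """
    adj = signed_adjacency(changes, beta)
    tom = topological_overlap(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim.values, 0.0)
    raw_labels = cut_tree_dynamic(dissim, deep_split=deep_split, min_size=min_size)
    if (raw_labels > 0).sum() == 0:
        partition = ModulePartition(
            labels=pd.Series(UNASSIGNED, index=changes.columns),
            eigenvectors=pd.DataFrame(index=changes.index),
            explained_variance={},
            params={},
        )
    else:
        partition = merge_modules(raw_labels, changes, merge_threshold)
        partition = assign_colors(partition)
        hub_metabolites(adj, partition)
    partition.params.update(
        {
            "beta": int(beta),
            "deep_split": int(deep_split),
            "min_size": int(min_size),
            "merge_threshold": float(merge_threshold),
        }
    )
    return partition, adj, tom
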