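"""Multivariate structure: PCA, DAPC, sample dendrograms and minimum
spanning networks.

DAPC (discriminant analysis of principal components) summarizes genetic
structure among predefined groups: genotypes are reduced by PCA, then linear
discriminant analysis separates the groups in the reduced space.  The
minimum spanning network connects multilocus genotypes by the smallest
distances and keeps tied alternatives as reticulations, which suits clonal
collections where several nodes may be equally close.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ValidationError
from .io import DistanceMatrix, GenotypeMatrix


@dataclass
class OrdinationResult:
    """PCA (and optionally DAPC) output.

    ``eigenvalues`` and ``explained_variance_ratio`` cover *all* computed
    axes; ``scores`` holds the retained axes only.  For DAPC the
    discriminant fields are filled and ``cumulative_variance`` refers to the
    PCA axes retained before discrimination.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    n_axes: int
    cumulative_variance: float
    discriminant_scores: pd.DataFrame | None = None
    group_assignment: pd.Series | None = None
    posterior: pd.DataFrame | None = None
    n_discriminants: int | None = None


def _centered_imputed(G: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing dosages per locus, then center each locus."""
    X = G.dosage.copy()
    nan = np.isnan(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    X[nan] = np.broadcast_to(mean, X.shape)[nan]
    return X - X.mean(axis=0)


def pca(G: GenotypeMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal components of the centered (unscaled) dosage matrix.

    Missing cells are mean-imputed per locus (they then sit at the locus
    centroid and contribute nothing to the covariance).  Eigenvalues are
    those of the sample covariance matrix; variance fractions are reported
    over all computed axes and sum to 1.
    """
    Xc = _centered_imputed(G)
    n = G.n_samples
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    ratio = eig / total if total > 0 else np.zeros_like(eig)
    available = len(eig)
    if n_axes is None:
        n_axes = available
    elif n_axes > available:
        warnings.warn(
            f"requested {n_axes} axes but only {available} available; truncating",
            stacklevel=2,
        )
        n_axes = available
    scores = pd.DataFrame(
        (U * s)[:, :n_axes],
        index=G.sample_ids,
        columns=[f"PC{k + 1}" for k in range(n_axes)],
    )
    return OrdinationResult(
        scores=scores,
        eigenvalues=eig,
        explained_variance_ratio=ratio,
        n_axes=n_axes,
        cumulative_variance=float(ratio[:n_axes].sum()),
    )


def dapc(G: GenotypeMatrix, grouping, n_pca_axes: int = 100) -> OrdinationResult:
    """Discriminant analysis of principal components with given group priors.

    PCA scores (``n_pca_axes`` retained) feed a linear discriminant
    analysis; at most (number of groups - 1) discriminant functions exist,
    and each sample is assigned to the group with the highest posterior.
    """
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    groups = grouping.loc[G.sample_ids]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValidationError("DAPC needs at least 2 groups")
    singletons = list(counts.index[counts < 2])
    if singletons:
        raise ValidationError(
            f"groups with a single sample (within-group covariance undefined): {singletons}"
        )
    base = pca(G, n_axes=min(n_pca_axes, G.n_samples - 1, G.n_loci))
    lda = LinearDiscriminantAnalysis()
    lda.fit(base.scores.to_numpy(), groups.to_numpy())
    ld = lda.transform(base.scores.to_numpy())
    classes = list(lda.classes_)
    return OrdinationResult(
        scores=base.scores,
        eigenvalues=base.eigenvalues,
        explained_variance_ratio=base.explained_variance_ratio,
        n_axes=base.n_axes,
        cumulative_variance=base.cumulative_variance,
        discriminant_scores=pd.DataFrame(
            ld, index=G.sample_ids, columns=[f"LD{k + 1}" for k in range(ld.shape[1])]
        ),
        group_assignment=pd.Series(lda.predict(base.scores.to_numpy()), index=G.sample_ids),
        posterior=pd.DataFrame(
            lda.predict_proba(base.scores.to_numpy()), index=G.sample_ids, columns=classes
        ),
        n_discriminants=ld.shape[1],
    )


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def sample_dendrogram(D: DistanceMatrix, method: str = "upgma") -> dendropy.Tree:
    """UPGMA (default) or NJ tree over samples.

    UPGMA yields an ultrametric tree (every leaf at equal depth), which is
    what a fixed-height duplicate cut on a dendrogram assumes; clone
    duplicates at distance ~0 appear as near-zero-height cherries.
    """
    if method == "nj":
        from .diversity import neighbor_joining

        return neighbor_joining(D)
    if method != "upgma":
        raise ValueError("method must be 'upgma' or 'nj'")
    if D.n < 2:
        raise ValidationError("dendrogram needs at least 2 samples")
    if np.isnan(D.values).any():
        raise ValidationError(f"undefined distances: {D.undefined_pairs()[:5]}")
    Z = linkage(squareform(D.values, checks=False), method="average")
    root = to_tree(Z)
    labels = [_quote(s) for s in D.ids]

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        ltxt, lh = rec(node.left)
        rtxt, rh = rec(node.right)
        h = node.dist / 2.0
        return f"({ltxt}:{h - lh:.12g},{rtxt}:{h - rh:.12g})", h

    txt, _ = rec(root)
    return dendropy.Tree.get(data=txt + ";", schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------


def minimum_spanning_network(
    D: DistanceMatrix,
    tie_tolerance: float = 1e-9,
    node_attributes: dict[str, dict] | None = None,
) -> nx.Graph:
    """Minimum spanning tree plus tied alternative edges (reticulations).

    A non-tree edge (u, v) is added as a reticulation when its weight ties
    (within ``tie_tolerance``) the maximum-weight edge on the tree path
    u -> v — i.e. swapping it in would give another minimum spanning tree.
    Edge attribute ``kind`` is ``"mst"`` or ``"reticulation"``.
    """
    if np.isnan(D.values).any():
        raise ValidationError(f"undefined distances: {D.undefined_pairs()[:5]}")
    full = nx.Graph()
    full.add_nodes_from(D.ids)
    for i, u in enumerate(D.ids):
        for j in range(i + 1, D.n):
            full.add_edge(u, D.ids[j], weight=float(D.values[i, j]))
    mst = nx.minimum_spanning_tree(full, weight="weight")
    net = nx.Graph()
    net.add_nodes_from(D.ids)
    for u, v, data in mst.edges(data=True):
        net.add_edge(u, v, weight=data["weight"], kind="mst")
    for u, v, data in full.edges(data=True):
        if net.has_edge(u, v):
            continue
        path = nx.shortest_path(mst, u, v)
        path_max = max(
            mst.edges[a, b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if data["weight"] <= path_max + tie_tolerance:
            net.add_edge(u, v, weight=data["weight"], kind="reticulation")
    if node_attributes:
        nx.set_node_attributes(net, node_attributes)
    return net


def msn_over_clones(D: DistanceMatrix, partition, meta=None) -> nx.Graph:
    """Minimum spanning network over clone representatives.

    Nodes are multilocus genotypes (one representative per clone group),
    annotated with their member samples and, when metadata is given, the
    zones the clone was collected in.
    """
    reps = [partition.representative[g] for g in sorted(partition.groups)]
    sub = D.submatrix(reps)
    attrs: dict[str, dict] = {}
    for g in sorted(partition.groups):
        rep = partition.representative[g]
        members = list(partition.groups[g])
        a: dict = {"group": g, "members": members, "n_members": len(members)}
        if meta is not None:
            zones = sorted(
                {
                    str(meta.table.loc[s, "zone"])
                    for s in members
                    if s in meta.table.index and pd.notna(meta.table.loc[s, "zone"])
                }
            )
            a["zones"] = zones
        attrs[rep] = a
    return minimum_spanning_network(sub, node_attributes=attrs)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        (u, v, data["weight"], data["kind"]) for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "kind"]).to_csv(
        path, sep="\t", index=False
    )
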