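"""Rooting-type classification: z-scores, PCA, hierarchical clustering,
small/medium/large labelling, and HP->LP transition analysis.

Genotype trait means within one environment are standardized
column-wise, decomposed by PCA (for biplots and variance shares), and
clustered by hierarchical agglomeration on Euclidean distances of the
z-scored rows.  The tree is cut into k = 3 groups, which are ranked by
the mean z-score of the size-category traits to yield the rooting
types "small", "medium" and "large".  Comparing each genotype's type
at high and low phosphorus gives a 3 x 3 transition matrix and the
share of genotypes that keep their type, shift one category, or jump
two.  Both dendrograms can be serialized as Newick trees for
tanglegram rendering.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .traits import SIZE_CATEGORY_TRAITS

__all__ = [
    "ZMatrix",
    "PcaModel",
    "ClusterLabels",
    "TransitionSummary",
    "zscore",
    "pca",
    "cluster",
    "assign_size_labels",
    "transition_matrix",
    "linkage_to_newick",
    "tanglegram_export",
    "plot_tanglegram",
    "SIZE_LABEL_ORDER",
]

SIZE_LABEL_ORDER = ("small", "medium", "large")


@dataclass
class ZMatrix:
    """Genotype x trait matrix of column-wise z-scores."""

    values: pd.DataFrame
    dropped: tuple[str, ...] = ()

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PcaModel:
    """Loadings, scores and variance shares of a trait-space PCA."""

    loadings: pd.DataFrame       # trait x component
    scores: pd.DataFrame         # genotype x component
    var_pct: np.ndarray          # percentage of variance per component
    sign_anchor: str = ""        # trait used to orient Dim1


@dataclass
class ClusterLabels:
    """Cluster assignment (and optional size label) per genotype."""

    cluster: pd.Series                    # genotype -> cluster id in 1..k
    linkage_matrix: np.ndarray
    size_label: pd.Series | None = None
    environment: str = ""

    @property
    def genotypes(self) -> list[str]:
        return list(self.cluster.index)

    @property
    def k(self) -> int:
        return int(self.cluster.nunique())


@dataclass
class TransitionSummary:
    """HP->LP rooting-type transitions, row-normalized percentages."""

    matrix_pct: pd.DataFrame     # rows HP categories, columns LP categories
    counts: pd.DataFrame
    same_pct: float
    one_step_pct: float
    two_step_pct: float


def zscore(means: pd.DataFrame) -> ZMatrix:
    """Column-wise z-scores (x - mean) / s.d. of genotype trait means.

    Constant columns cannot be standardized and are dropped with a
    warning naming the trait.
    """
    if means.shape[0] < 2:
        raise ValueError("z-scores need at least 2 genotypes")
    sd = means.std(ddof=1)
    constant = tuple(str(c) for c in means.columns[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"dropping constant trait column(s): {', '.join(constant)}")
    kept = means.drop(columns=list(constant))
    z = (kept - kept.mean()) / kept.std(ddof=1)
    return ZMatrix(values=z, dropped=constant)


def pca(z: ZMatrix, sign_anchor: str = "NeL") -> PcaModel:
    """PCA of the z-scored trait matrix.

    Components are eigenvectors of the trait correlation structure;
    variance percentages are over all components and sum to 100.  The
    first component is oriented so the ``sign_anchor`` trait (network
    length by default, the canonical size trait) loads non-negatively;
    remaining components are oriented by their largest-|loading| trait.
    """
    X = z.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "z-matrix contains missing values; impute or drop rows first")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 genotypes")
    from sklearn.decomposition import PCA as _PCA

    n_comp = min(n, p)
    model = _PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T          # trait x component
    var_pct = model.explained_variance_ratio_ * 100.0

    anchor_idx = z.traits.index(sign_anchor) if sign_anchor in z.traits else None
    for c in range(n_comp):
        if c == 0 and anchor_idx is not None:
            ref = loadings[anchor_idx, c]
        else:
            ref = loadings[np.argmax(np.abs(loadings[:, c])), c]
        if ref < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"Dim{i + 1}" for i in range(n_comp)]
    return PcaModel(
        loadings=pd.DataFrame(loadings, index=z.traits, columns=comp_names),
        scores=pd.DataFrame(scores, index=z.genotypes, columns=comp_names),
        var_pct=var_pct,
        sign_anchor=sign_anchor if anchor_idx is not None else "",
    )


def cluster(z: ZMatrix, k: int = 3, linkage: str = "complete",
            environment: str = "") -> ClusterLabels:
    """Hierarchical agglomerative clustering of z-scored genotypes.

    Euclidean distances, linkage method selectable (complete by
    default; ward/average/single supported), tree cut into ``k``
    groups.  Cluster ids are renumbered 1..k in order of first
    appearance so the labelling is deterministic for a given input
    order.
    """
    n = z.values.shape[0]
    if k > n:
        raise ValueError(f"cannot form k={k} clusters from {n} genotypes")
    Z = hierarchy.linkage(z.values.to_numpy(dtype=float), method=linkage,
                          metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return ClusterLabels(
        cluster=pd.Series(labels, index=z.genotypes, name="cluster"),
        linkage_matrix=Z,
        environment=environment,
    )


def assign_size_labels(labels: ClusterLabels, z: ZMatrix) -> ClusterLabels:
    """Rank the three clusters by root-system size and label them.

    Size is the mean z-score over the size-category traits (NeA, NeL,
    NeP, NeSA, NeV — average root width excluded, as it runs against
    the rest of the size block); the lowest-scoring cluster is
    "small", the highest "large".  Ties are broken by mean NeL, then
    by cluster id.
    """
    ids = sorted(labels.cluster.unique())
    if len(ids) != 3:
        raise ValueError(f"size labelling needs exactly 3 clusters, got {len(ids)}")
    size_cols = [t for t in SIZE_CATEGORY_TRAITS if t in z.values.columns]
    if not size_cols:
        size_cols = list(z.values.columns)      # generic data: use everything
    nel = z.values["NeL"] if "NeL" in z.values.columns else z.values[size_cols].mean(axis=1)

    keyed = []
    for cid in ids:
        members = labels.cluster.index[labels.cluster == cid]
        score = float(z.values.loc[members, size_cols].mean().mean())
        keyed.append((score, float(nel.loc[members].mean()), cid))
    keyed.sort()
    mapping = {cid: SIZE_LABEL_ORDER[rank] for rank, (_, _, cid) in enumerate(keyed)}
    size = labels.cluster.map(mapping).rename("size_label")
    return ClusterLabels(cluster=labels.cluster, linkage_matrix=labels.linkage_matrix,
                         size_label=size, environment=labels.environment)


def transition_matrix(hp: ClusterLabels, lp: ClusterLabels) -> TransitionSummary:
    """HP->LP rooting-type transition percentages.

    Rows are HP categories (small, medium, large), row-normalized to
    100%.  The summary partitions all genotypes into same-category,
    one-step and two-step changes.
    """
    if hp.size_label is None or lp.size_label is None:
        raise ValueError("both label sets need size labels (run assign_size_labels)")
    only_hp = set(hp.genotypes) - set(lp.genotypes)
    only_lp = set(lp.genotypes) - set(hp.genotypes)
    if only_hp or only_lp:
        raise ValueError(
            f"genotype sets differ: only-HP {sorted(only_hp)[:5]}, "
            f"only-LP {sorted(only_lp)[:5]}"
        )
    order = list(SIZE_LABEL_ORDER)
    hp_lab = hp.size_label
    lp_lab = lp.size_label.reindex(hp_lab.index)
    counts = pd.crosstab(hp_lab, lp_lab).reindex(index=order, columns=order,
                                                 fill_value=0)
    counts.index.name, counts.columns.name = "HP", "LP"
    row_sums = counts.sum(axis=1)
    pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0

    rank = {c: i for i, c in enumerate(order)}
    steps = np.abs(hp_lab.map(rank).to_numpy() - lp_lab.map(rank).to_numpy())
    n = len(steps)
    return TransitionSummary(
        matrix_pct=pct,
        counts=counts,
        same_pct=100.0 * float((steps == 0).sum()) / n,
        one_step_pct=100.0 * float((steps == 1).sum()) / n,
        two_step_pct=100.0 * float((steps == 2).sum()) / n,
    )


def _to_newick(node: hierarchy.ClusterNode, names: list[str],
               parent_dist: float) -> str:
    length = max(parent_dist - node.dist, 0.0)
    if node.is_leaf():
        return f"{names[node.id]}:{length:.10g}"
    parts = [_to_newick(ch, names, node.dist)
             for ch in (node.left, node.right) if ch is not None]
    # canonical child order: by smallest leaf name, so the serialization
    # is invariant to the input row order
    parts.sort(key=_min_leaf_key)
    return f"({','.join(parts)}):{length:.10g}"


def _min_leaf_key(newick_part: str) -> str:
    leaves = [tok.split(":")[0].strip("()")
              for tok in newick_part.replace("(", "").split(",")]
    return min(leaves)


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a rooted Newick tree with
    branch lengths derived from merge heights, in a canonical child
    order (invariant to input permutation for tie-free data)."""
    root = hierarchy.to_tree(Z)
    return _to_newick(root, list(names), root.dist) + ";"


def tanglegram_export(hp: ClusterLabels, lp: ClusterLabels) -> dict:
    """Serialize the HP and LP dendrograms plus the genotype mapping.

    Returns Newick strings for both trees and a mapping table with one
    row per genotype giving its leaf position in each dendrogram's
    display order and its cluster / size label in each environment —
    everything needed to draw the auxiliary lines of a tanglegram.
    """
    if set(hp.genotypes) != set(lp.genotypes):
        raise ValueError("tanglegram needs identical genotype sets in HP and LP")
    names = hp.genotypes
    nwk_hp = linkage_to_newick(hp.linkage_matrix, names)
    nwk_lp = linkage_to_newick(lp.linkage_matrix, lp.genotypes)

    hp_order = hierarchy.leaves_list(hp.linkage_matrix)
    lp_order = hierarchy.leaves_list(lp.linkage_matrix)
    hp_pos = {names[leaf]: pos for pos, leaf in enumerate(hp_order)}
    lp_names = lp.genotypes
    lp_pos = {lp_names[leaf]: pos for pos, leaf in enumerate(lp_order)}
    mapping = pd.DataFrame({
        "genotype": names,
        "hp_leaf_order": [hp_pos[g] for g in names],
        "lp_leaf_order": [lp_pos[g] for g in names],
        "hp_cluster": hp.cluster.reindex(names).to_numpy(),
        "lp_cluster": lp.cluster.reindex(names).to_numpy(),
    })
    if hp.size_label is not None:
        mapping["hp_size"] = hp.size_label.reindex(names).to_numpy()
    if lp.size_label is not None:
        mapping["lp_size"] = lp.size_label.reindex(names).to_numpy()
    return {"hp_newick": nwk_hp, "lp_newick": nwk_lp, "mapping": mapping}


def plot_tanglegram(hp: ClusterLabels, lp: ClusterLabels, out_path: str):
    """Render a side-by-side HP/LP tanglegram with connecting lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_l, ax_m, ax_r) = plt.subplots(
        1, 3, figsize=(10, max(4, 0.12 * len(hp.genotypes))),
        gridspec_kw={"width_ratios": [4, 2, 4]})
    dl = hierarchy.dendrogram(hp.linkage_matrix, orientation="left",
                              labels=hp.genotypes, ax=ax_l, no_labels=True)
    dr = hierarchy.dendrogram(lp.linkage_matrix, orientation="right",
                              labels=lp.genotypes, ax=ax_r, no_labels=True)
    pos_l = {g: i for i, g in enumerate(dl["ivl"])}
    pos_r = {g: i for i, g in enumerate(dr["ivl"])}
    for g in hp.genotypes:
        ax_m.plot([0, 1], [pos_l[g], pos_r[g]], lw=0.5, color="gray")
    ax_m.set_axis_off()
    ax_l.set_title("HP")
    ax_r.set_title("LP")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
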