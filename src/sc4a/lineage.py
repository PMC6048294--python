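"""Lineage and pseudotime analysis of ordination cell scores.

Cells are clustered in score space with a Gaussian mixture (EM); a minimum
spanning tree over the cluster centroids supplies the lineage skeleton.
Root-to-leaf paths are lineages; clusters of MST degree >= 3 shared by two
or more lineages are bifurcation points.  A cell's pseudotime along a
lineage is its arc-length position on the piecewise-linear curve through the
lineage's ordered centroids, rescaled to [0, 1].  Pseudotime orders cells by
transcriptional similarity; it is not a measurement of physical time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger("sc4a")


@dataclass
class LineageModel:
    cell_ids: list[str]
    cluster_labels: np.ndarray  # per cell, int
    centroids: np.ndarray  # n_clusters x n_axes
    mst_edges: list[tuple[int, int]]
    root: int
    lineages: list[list[int]]  # ordered cluster paths, root first
    bifurcation_clusters: list[int]
    pseudotime: pd.DataFrame = field(default_factory=pd.DataFrame)  # cell x lineage

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def to_dict(self) -> dict:
        return dict(
            n_clusters=self.n_clusters,
            root=self.root,
            mst_edges=[list(e) for e in self.mst_edges],
            lineages=[list(l) for l in self.lineages],
            bifurcation_clusters=list(self.bifurcation_clusters),
        )


def em_cluster(
    scores: np.ndarray,
    K: int | Sequence[int],
    seed: int,
    n_init: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-mixture EM clustering of cell scores; BIC model selection
    when K is a range.  Returns (labels, centroids)."""
    scores = np.asarray(scores, dtype=float)
    ks = [K] if isinstance(K, (int, np.integer)) else list(K)
    if max(ks) >= scores.shape[0]:
        raise ValidationError("K must be below the number of cells")
    best, best_bic = None, np.inf
    for k in ks:
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed).fit(scores)
        bic = gm.bic(scores)
        if bic < best_bic:
            best, best_bic = gm, bic
    labels = best.predict(scores)
    if len(ks) > 1:
        logger.info("BIC selected K=%d", best.n_components)
    # centroids as empirical means of assigned cells (stable for MST geometry)
    centroids = np.vstack([
        scores[labels == c].mean(axis=0) if np.any(labels == c) else best.means_[c]
        for c in range(best.n_components)
    ])
    return labels, centroids


def build_lineages(
    centroids: np.ndarray,
    root: int | None = None,
    root_arrow: np.ndarray | None = None,
    cell_ids: Sequence[str] | None = None,
    cluster_labels: np.ndarray | None = None,
) -> LineageModel:
    """Euclidean MST over cluster centroids, root choice, and lineage paths.

    The root is either fixed (``root``) or chosen as the cluster whose
    centroid direction best aligns (cosine) with ``root_arrow`` — typically
    the biplot arrow of the resting/naive covariate.  Lineages are the
    root-to-leaf paths of the tree; MST ties break lexicographically.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    if n < 2:
        raise ValidationError("at least 2 clusters are required")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        G.add_edge(i, j, weight=float(np.linalg.norm(centroids[i] - centroids[j])))
    # kruskal with stable sorting; insertion order (lexicographic) breaks ties
    T = nx.minimum_spanning_tree(G, algorithm="kruskal")
    if root is None:
        if root_arrow is None:
            raise ValueError("provide either root or root_arrow")
        arrow = np.asarray(root_arrow, dtype=float)
        norms = np.linalg.norm(centroids, axis=1) * np.linalg.norm(arrow)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = np.where(norms > 0, centroids @ arrow / norms, -np.inf)
        root = int(np.argmax(cos))
    leaves = sorted(v for v in T.nodes if T.degree[v] == 1 and v != root)
    if not leaves:  # root is the single leaf of a 2-node tree edge case
        leaves = [v for v in T.nodes if v != root]
    lineages = [nx.shortest_path(T, root, leaf) for leaf in leaves]
    bifurcation = sorted(
        v for v in T.nodes
        if T.degree[v] >= 3 and sum(v in path for path in lineages) >= 2
    )
    return LineageModel(
        cell_ids=list(cell_ids) if cell_ids is not None else [],
        cluster_labels=(np.asarray(cluster_labels)
                        if cluster_labels is not None else np.zeros(0, dtype=int)),
        centroids=centroids,
        mst_edges=sorted(tuple(sorted(e)) for e in T.edges),
        root=int(root),
        lineages=lineages,
        bifurcation_clusters=bifurcation,
    )


def _project_polyline(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's orthogonal projection onto the
    piecewise-linear curve through ``nodes`` (nearest segment wins)."""
    seglens = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    total = cum[-1]
    best_pos = np.zeros(points.shape[0])
    best_d2 = np.full(points.shape[0], np.inf)
    for s in range(len(nodes) - 1):
        a, b = nodes[s], nodes[s + 1]
        ab = b - a
        L2 = ab @ ab
        t = np.clip((points - a) @ ab / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(points))
        proj = a + t[:, None] * ab
        d2 = np.sum((points - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_pos[better] = cum[s] + t[better] * seglens[s]
    return best_pos / total if total > 0 else best_pos


def assign_pseudotime(
    scores: np.ndarray,
    model: LineageModel,
    lineage_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell, per-lineage pseudotime in [0, 1].

    A cell participates in a lineage iff its cluster lies on that lineage's
    path (shared trunk clusters belong to every lineage through them); other
    cells carry NaN for that lineage.  Results are stored on the model too.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(model.cluster_labels):
        raise ValidationError("scores and cluster labels refer to different cells")
    names = (list(lineage_names) if lineage_names is not None
             else [f"lineage_{i}" for i in range(len(model.lineages))])
    out = pd.DataFrame(np.nan, index=model.cell_ids or range(scores.shape[0]), columns=names)
    for name, path in zip(names, model.lineages):
        on_path = np.isin(model.cluster_labels, path)
        if not on_path.any():
            continue
        nodes = model.centroids[path]
        out.loc[out.index[on_path], name] = _project_polyline(scores[on_path], nodes)
    orphan = int((~np.isin(model.cluster_labels,
                           sorted({c for p in model.lineages for c in p}))).sum())
    if orphan:
        logger.info("%d cell(s) lie in no lineage path cluster", orphan)
    model.pseudotime = out
    return out


def module_trajectory(
    X: ExpressionMatrix,
    genes: GeneSet,
    pseudotime: pd.Series | np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Binned mean of summed standardized expression along pseudotime.

    Each present module gene is z-scored across cells (zero-variance genes
    contribute 0); the per-cell module value is the sum of z-scores, averaged
    within equal-width pseudotime bins on [0, 1].
    """
    present = [g for g in X.col_ids if g in genes]
    skipped = len(genes) - len(present)
    if skipped:
        logger.info("module_trajectory: %d module gene(s) absent, skipped", skipped)
    if not present:
        raise ValidationError(f"no member of gene set {genes.name!r} is present")
    idx = [X.col_ids.index(g) for g in present]
    sub = X.values[:, idx]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    module = z.sum(axis=1)
    t = (pseudotime.to_numpy() if isinstance(pseudotime, pd.Series)
         else np.asarray(pseudotime, dtype=float))
    ok = ~np.isnan(t)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(t[ok], edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        vals = module[ok][which == b]
        rows.append(dict(
            bin=b,
            t_mid=float((edges[b] + edges[b + 1]) / 2),
            mean=float(vals.mean()) if vals.size else np.nan,
            sd=float(vals.std()) if vals.size else np.nan,
            n=int(vals.size),
        ))
    return pd.DataFrame(rows)


def quadrant_gate(
    X: ExpressionMatrix,
    gene_x: str,
    gene_y: str,
    tx: float,
    ty: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flow-cytometry-style 2x2 quadrant counts on two genes.

    Quadrants: ``pp`` (x>tx, y>ty), ``pn`` (x>tx, y<=ty), ``np`` (x<=tx,
    y>ty), ``nn`` (x<=tx, y<=ty).  Percentages sum to 100.
    """
    for g in (gene_x, gene_y):
        if g not in X.col_ids:
            raise ValidationError(f"gene {g!r} absent from the matrix")
    x = X.values[:, X.col_ids.index(gene_x)]
    y = X.values[:, X.col_ids.index(gene_y)]
    labels = np.where(x > tx, np.where(y > ty, "pp", "pn"), np.where(y > ty, "np", "nn"))
    counts = {q: int(np.sum(labels == q)) for q in ("pp", "pn", "np", "nn")}
    total = sum(counts.values())
    table = pd.DataFrame(
        dict(quadrant=list(counts), count=list(counts.values()),
             percent=[100.0 * c / total for c in counts.values()])
    )
    return table, pd.Series(labels, index=X.row_ids, name="quadrant")


def set_intersections(sets: Mapping[str, GeneSet | set]) -> pd.DataFrame:
    """Cardinality of every region of the Venn partition of up to 5 sets.

    Each region is keyed by the subset of set names whose members belong to
    exactly those sets (2^s - 1 nonempty regions).  Also usable for the
    pairwise overlap table via the ``in_sets`` column.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("at least 2 sets are required")
    if len(names) > 5:
        raise ValidationError("more than 5 sets: Venn partition guard")
    member_sets = {
        n: set(s.members if isinstance(s, GeneSet) else s) for n, s in sets.items()
    }
    universe = set().union(*member_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            regions[combo] = 0
    for g in universe:
        membership = tuple(n for n in names if g in member_sets[n])
        regions[membership] += 1
    rows = [dict(in_sets="&".join(combo), n_sets=len(combo), exclusive_count=cnt)
            for combo, cnt in regions.items()]
    df = pd.DataFrame(rows)
    # total overlap of each combo = sum of exclusive regions containing it
    totals = []
    for combo in regions:
        members = set(combo)
        totals.append(sum(
            cnt for other, cnt in regions.items() if members <= set(other)
        ))
    df["total_count"] = totals
    return df
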