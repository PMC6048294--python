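"""Single-cell matrix preparation: gene filtering, in-silico gating, and
PCA + k-means outlier removal.

Operates on matrices in cells-by-genes orientation (cells are rows).  Every
stage records its attrition so the (necessarily heuristic) thresholds are
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, Orientation, ValidationError, validate_expression

logger = logging.getLogger("sc4a")


@dataclass
class GateSpec:
    marker: str
    op: str = "gt"  # gt | ge
    threshold: float = 0.0

    def passes(self, values: np.ndarray) -> np.ndarray:
        if self.op == "gt":
            return values > self.threshold
        if self.op == "ge":
            return values >= self.threshold
        raise ValueError(f"unknown gate op {self.op!r}")


@dataclass
class AttritionReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, stage: str, cells_in: int, cells_out: int, genes_in: int, genes_out: int) -> None:
        self.rows.append(dict(stage=stage, cells_in=cells_in, cells_out=cells_out,
                              genes_in=genes_in, genes_out=genes_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _require_cells_by_genes(X: ExpressionMatrix) -> None:
    if X.orientation != Orientation.CELLS_BY_GENES:
        raise ValidationError("this operation requires cells_by_genes orientation")


def filter_genes_sc(
    X: ExpressionMatrix,
    min_variance: float | None = None,
    min_max: float | None = None,
    report: AttritionReport | None = None,
) -> ExpressionMatrix:
    """Drop genes with BOTH low variance AND low maximal expression.

    A gene is removed only if it fails both criteria (variance <
    ``min_variance`` and max < ``min_max``), so a spike-like gene with zero
    variance in most cells but a high maximum survives.  Defaults place both
    thresholds at the 10th percentile of their per-gene distributions.
    """
    _require_cells_by_genes(X)
    var = X.values.var(axis=0)
    mx = X.values.max(axis=0)
    if min_variance is None:
        min_variance = float(np.quantile(var, 0.10))
    if min_max is None:
        min_max = float(np.quantile(mx, 0.10))
    drop = (var < min_variance) & (mx < min_max)
    if drop.all():
        raise ValidationError("gene filter would remove every gene")
    keep = [g for g, d in zip(X.col_ids, drop) if not d]
    logger.info("filter_genes_sc: %d/%d genes removed", int(drop.sum()), X.m)
    out = X.subset_cols(keep)
    if report is not None:
        report.add("filter_genes", X.p, out.p, X.m, out.m)
    return out


def in_silico_gate(
    X: ExpressionMatrix,
    gates: list[GateSpec],
    report: AttritionReport | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Keep cells passing ALL gates (conjunction); e.g. CD4+CD3E+ selection.

    Returns the gated matrix and a per-cell boolean label series for the
    original cells.  Default gates test for any positive expression of the
    marker (threshold 0, strict).
    """
    _require_cells_by_genes(X)
    mask = np.ones(X.p, dtype=bool)
    attrition = []
    col_index = {g: i for i, g in enumerate(X.col_ids)}
    for gate in gates:
        if gate.marker not in col_index:
            raise ValidationError(f"gate marker {gate.marker!r} absent from the matrix")
        ok = gate.passes(X.values[:, col_index[gate.marker]])
        attrition.append((gate.marker, int((mask & ~ok).sum())))
        mask &= ok
    if gates and not mask.any():
        table = ", ".join(f"{m}: -{n}" for m, n in attrition)
        raise ValidationError(f"no cell passes all gates (attrition: {table})")
    labels = pd.Series(mask, index=X.row_ids, name="passed")
    out = X.subset_rows([c for c, k in zip(X.row_ids, mask) if k]) if gates else X
    if report is not None:
        report.add("gate", X.p, out.p, X.m, out.m)
    return out, labels


def pca_kmeans_outlier_removal(
    X: ExpressionMatrix,
    n_components: int = 10,
    k: int = 2,
    drop_policy: str = "smallest_cluster",
    seed: int | None = None,
    n_init: int = 10,
    max_drop_fraction: float = 0.20,
    report: AttritionReport | None = None,
) -> ExpressionMatrix:
    """Remove outlier cells by k-means clustering of the PCA cell plot.

    Cells are embedded by PCA (centered, unscaled), clustered by k-means with
    a fixed seed, and the outlier cluster is dropped: the smallest cluster
    (``smallest_cluster``) or the cluster whose centroid lies farthest from
    the overall centroid (``farthest_centroid``).  Removing more than
    ``max_drop_fraction`` of cells is an error, never silent.
    """
    _require_cells_by_genes(X)
    if seed is None:
        raise ValueError("a seed is required for deterministic outlier removal")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= X.p:
        raise ValidationError(f"k={k} must be below the number of cells ({X.p})")
    n_components = min(n_components, X.p - 1, X.m)
    emb = PCA(n_components=n_components, random_state=seed).fit_transform(X.values)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(emb)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    if drop_policy == "smallest_cluster":
        drop_cluster = int(np.argmin(sizes))
    elif drop_policy == "farthest_centroid":
        center = emb.mean(axis=0)
        dists = np.linalg.norm(km.cluster_centers_ - center, axis=1)
        if np.allclose(dists, dists[0]):
            logger.info("farthest_centroid: all centroids equidistant; keeping all cells")
            if report is not None:
                report.add("outlier_removal", X.p, X.p, X.m, X.m)
            return X
        drop_cluster = int(np.argmax(dists))
    else:
        raise ValueError(f"unknown drop_policy {drop_policy!r}")
    drop = labels == drop_cluster
    frac = drop.mean()
    if frac > max_drop_fraction:
        raise ValidationError(
            f"outlier removal would drop {frac:.1%} of cells "
            f"(> max_drop_fraction={max_drop_fraction:.0%}); adjust k or the policy"
        )
    keep = [c for c, d in zip(X.row_ids, drop) if not d]
    logger.info("outlier removal: dropped cluster %d (%d cells)", drop_cluster, int(drop.sum()))
    out = X.subset_rows(keep)
    if report is not None:
        report.add("outlier_removal", X.p, out.p, X.m, out.m)
    return out
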