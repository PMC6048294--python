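"""Build standardized explanatory variables from comparison datasets.

A contrast between two groups of samples (e.g. activated vs resting T cells,
or factor-transduced vs empty-vector cells) yields per-gene log2 fold changes
and p-values; genes passing FDR and fold-change filters carry their log2FC
into a single explanatory column, zero elsewhere, which is then standardized
to mean 0 / variance 1 over the full gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ExplanatoryMatrix, GeneSet, ValidationError

logger = logging.getLogger("sc4a")


@dataclass
class ContrastResult:
    gene_ids: list[str]
    log2fc: np.ndarray
    stat: np.ndarray | None
    p: np.ndarray | None
    fdr: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2fc": self.log2fc,
                "stat": self.stat if self.stat is not None else np.nan,
                "p": self.p if self.p is not None else np.nan,
                "fdr": self.fdr if self.fdr is not None else np.nan,
            },
            index=self.gene_ids,
        )


def _moderated_t(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics with pooled-prior variance shrinkage.

    Gene-wise pooled variances are shrunk toward their mean with a prior
    degrees-of-freedom d0 solved by method of moments from the excess
    dispersion of the variances:  Var(s^2) = s0^4 (2/d + 2/d0).  When the
    observed dispersion is at or below the chi-square expectation, shrinkage
    is complete (d0 effectively infinite).
    """
    nA, nB = A.shape[1], B.shape[1]
    d = nA + nB - 2
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    s2 = ((nA - 1) * vA + (nB - 1) * vB) / d
    s0 = float(s2.mean())
    if s0 <= 0:
        s0 = np.finfo(float).tiny
    excess = float(s2.var(ddof=1)) / (s0**2) - 2.0 / d
    d0 = 2.0 / excess if excess > 1e-12 else np.inf
    d0 = min(d0, 1e8)
    s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
    se = np.sqrt(s2_tilde * (1.0 / nA + 1.0 / nB))
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=d + d0)
    return t, p


def differential_contrast(
    A: ExpressionMatrix | np.ndarray,
    B: ExpressionMatrix | np.ndarray,
    method: str = "welch",
    gene_ids: Sequence[str] | None = None,
) -> ContrastResult:
    """Per-gene differential contrast of two sample groups (A minus B).

    Values are assumed to be on the log2 scale, so the group mean difference
    is the log2 fold change.  ``welch`` runs an unequal-variance two-sample
    t-test; ``moderated`` shrinks gene-wise variances toward the mean
    variance (empirical-Bayes-style, method-of-moments prior df).  P-values
    are BH-adjusted.  With a single replicate per group only the log2FC is
    produced.
    """
    if isinstance(A, ExpressionMatrix):
        if not isinstance(B, ExpressionMatrix):
            raise TypeError("A and B must both be ExpressionMatrix or both arrays")
        if A.row_ids != B.row_ids:
            raise ValidationError(
                "gene universes of the two groups differ; run harmonize_genes first"
            )
        gene_ids = list(A.row_ids)
        A, B = A.values, B.values
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(A.shape[0])]
    if A.shape[0] != B.shape[0]:
        raise ValidationError("A and B must have the same number of genes")
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    if A.shape[1] < 2 or B.shape[1] < 2:
        logger.warning("fewer than 2 replicates per group; p-values unavailable")
        return ContrastResult(list(gene_ids), log2fc, None, None, None)
    if method == "welch":
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        t = np.nan_to_num(np.asarray(t), nan=0.0)
        p = np.nan_to_num(np.asarray(p), nan=1.0)
    elif method == "moderated":
        t, p = _moderated_t(A, B)
        p = np.nan_to_num(p, nan=1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    fdr = multipletests(p, method="fdr_bh")[1]
    return ContrastResult(list(gene_ids), log2fc, t, p, fdr)


def build_variable(
    contrast: ContrastResult,
    name: str = "variable",
    fdr_max: float = 0.01,
    abs_lfc_min: float = 1.0,
    top_n: int | None = None,
) -> tuple[ExplanatoryMatrix, GeneSet]:
    """One standardized explanatory column from a DEG-filtered contrast.

    Genes with FDR < ``fdr_max`` and |log2FC| > ``abs_lfc_min`` keep their
    log2FC; all other genes carry 0, keeping the column aligned with the full
    gene universe.  ``top_n`` optionally restricts to the smallest p-values.
    The column is standardized to mean 0, variance 1.
    """
    n_genes = len(contrast.gene_ids)
    if contrast.fdr is None:
        passing = np.abs(contrast.log2fc) > abs_lfc_min
        n_fdr = n_genes
    else:
        fdr_ok = contrast.fdr < fdr_max
        lfc_ok = np.abs(contrast.log2fc) > abs_lfc_min
        n_fdr = int(fdr_ok.sum())
        passing = fdr_ok & lfc_ok
    if top_n is not None and contrast.p is not None:
        idx = np.flatnonzero(passing)
        order = idx[np.argsort(contrast.p[idx], kind="stable")]
        keep = set(order[:top_n])
        passing = np.isin(np.arange(n_genes), list(keep))
    n_pass = int(passing.sum())
    if n_pass == 0:
        raise ValidationError(
            f"no gene passes the filters (of {n_genes}: {n_fdr} pass FDR<{fdr_max}, "
            f"0 also pass |log2FC|>{abs_lfc_min})"
        )
    col = np.where(passing, contrast.log2fc, 0.0)
    var = ExplanatoryMatrix(col[:, None], [name]).standardize()
    genes = GeneSet(name, {contrast.gene_ids[i] for i in np.flatnonzero(passing)})
    logger.info("variable %r built from %d/%d genes", name, n_pass, n_genes)
    return var, genes


def harmonize_genes(
    datasets: Sequence[ExpressionMatrix],
    mode: str = "exact",
) -> list[ExpressionMatrix]:
    """Align two or more expression matrices on their shared gene universe.

    The intersection of row ids is taken (case-folded in ``casefold`` mode)
    and every output is reindexed to the order of the shared genes as they
    appear in the first input.
    """
    if len(datasets) < 2:
        raise ValueError("harmonize_genes needs at least 2 inputs")
    if mode not in ("exact", "casefold"):
        raise ValueError(f"unknown mode {mode!r}")

    def key(g: str) -> str:
        return g.casefold() if mode == "casefold" else g

    keysets = [{key(g) for g in d.row_ids} for d in datasets]
    shared = set.intersection(*keysets)
    if not shared:
        raise ValidationError("gene universes have an empty intersection")
    ordered = [g for g in datasets[0].row_ids if key(g) in shared]
    out = []
    for d, ks in zip(datasets, keysets):
        dropped = len(d.row_ids) - len(ordered)
        if dropped:
            logger.info("harmonize: dropping %d gene(s) from a %d-gene input",
                        dropped, len(d.row_ids))
        by_key = {key(g): g for g in d.row_ids}
        out.append(d.subset_rows([by_key[key(g)] for g in ordered]))
    return out
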