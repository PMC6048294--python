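"""Synthetic fixture generators.

Emulates the statistical structure the analyses assume so every stage is
testable without external downloads:

* a paired activated-vs-resting bulk contrast (microarray-like log-normal
  log2 intensities, a planted set of induced genes);
* a single-cell matrix with discrete populations, each carrying one
  exclusive marker gene, several imperfect "decoy" markers, and a broader
  population signature (negative-binomial counts with dropout-style zeros);
* a branching (or chain) score-space trajectory for lineage/pseudotime
  analysis.

All generators are pure functions of their seed: the same seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .combinatorial import PopulationLabels
from .io import ExpressionMatrix, GeneSet, Orientation, validate_expression


@dataclass
class SingleCellTruth:
    """Planted structure of a simulated single-cell matrix."""

    labels: PopulationLabels
    markers: dict[str, str]  # population -> exclusive marker gene
    decoys: dict[str, list[str]]  # population -> imperfect markers
    signature: dict[str, list[str]]  # population -> broader signature genes

    @property
    def planted_genes(self) -> set[str]:
        """All genes carrying planted population structure; the complement
        of the gene universe is pure noise."""
        planted = set(self.markers.values())
        for d in self.decoys.values():
            planted.update(d)
        for s in self.signature.values():
            planted.update(s)
        return planted


@dataclass
class SimConfig:
    """Bundle of generator settings for the CLI `simulate` subcommand."""

    seed: int
    kind: str = "single_cells"  # single_cells | bulk_contrast | branching_scores
    n_genes: int = 300
    n_cells_or_samples: int = 500
    n_populations: int = 4
    dispersion: float = 0.3
    topology: str = "bifurcating"  # bifurcating | chain
    extra: dict = field(default_factory=dict)


def simulate_bulk_contrast(
    seed: int,
    n_genes: int = 500,
    n_per_group: int = 3,
    n_induced: int = 100,
    noise_sd: float = 0.7,
    effect_sd: float = 4.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneSet]:
    """Activated-vs-resting bulk contrast with a planted induced-gene set.

    Baseline log2 means are drawn log-normal-like (normal on the log2
    scale); induced genes are shifted upward in group A by
    ``effect_sd * noise_sd`` log2 units.  With the defaults the shift is
    2.8 log2 units over a replicate SD of 0.7 — a strong activation response
    affecting 20% of the (desk-scale) gene universe.  Returns
    (activated, resting, truth).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    baseline = rng.normal(6.0, 1.5, size=n_genes)
    effect = np.zeros(n_genes)
    induced = rng.choice(n_genes, size=n_induced, replace=False)
    effect[induced] = effect_sd * noise_sd
    A = baseline[:, None] + effect[:, None] + rng.normal(0, noise_sd, (n_genes, n_per_group))
    B = baseline[:, None] + rng.normal(0, noise_sd, (n_genes, n_per_group))
    A = np.clip(A, 0, None)
    B = np.clip(B, 0, None)
    # keep the gene universes aligned: drop a gene from both groups if it is
    # undetected (all-zero) in either
    ok = (A.sum(axis=1) > 0) & (B.sum(axis=1) > 0)
    genes_kept = [g for g, k in zip(genes, ok) if k]
    act = validate_expression(A[ok], genes_kept, [f"act_{j}" for j in range(n_per_group)])
    rest = validate_expression(B[ok], genes_kept, [f"rest_{j}" for j in range(n_per_group)])
    truth = GeneSet("induced", {genes[i] for i in induced if ok[i]})
    return act, rest, truth


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float | None
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with Var = mu + dispersion*mu^2.

    ``dispersion=None`` is the noise-free limit: the means themselves are
    returned, giving identical profiles within a population.
    """
    if dispersion is None:
        return mu.copy()
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_single_cells(
    seed: int,
    n_cells: int = 500,
    n_genes: int = 300,
    n_populations: int = 4,
    decoys_per_population: int = 4,
    signature_genes_per_population: int = 10,
    marker_mean: float = 30.0,
    decoy_fold: float = 3.0,
    signature_fold: float = 3.0,
    baseline_mean: float = 5.0,
    dispersion: float = 0.3,
) -> tuple[ExpressionMatrix, SingleCellTruth]:
    """Cells-by-genes count matrix with planted populations.

    Each population carries one *exclusive* marker (expressed in its cells
    only), ``decoys_per_population`` decoy markers (elevated
    ``decoy_fold``-fold in the population but expressed everywhere), and a
    broader ``signature_fold``-fold signature over
    ``signature_genes_per_population`` background genes.  Remaining genes are
    population-independent noise.  Returns (matrix, planted truth).
    """
    rng = np.random.default_rng(seed)
    pops = [f"pop{i+1}" for i in range(n_populations)]
    sizes = np.full(n_populations, n_cells // n_populations)
    sizes[: n_cells % n_populations] += 1
    membership = np.repeat(np.arange(n_populations), sizes)

    markers = {p: f"MARK_{p}" for p in pops}
    decoys = {p: [f"DECOY{d+1}_{p}" for d in range(decoys_per_population)] for p in pops}
    special = [markers[p] for p in pops] + [g for p in pops for g in decoys[p]]
    n_background = n_genes - len(special)
    if n_background < n_populations * signature_genes_per_population:
        raise ValueError("n_genes too small for the requested planted structure")
    background = [f"g{i:04d}" for i in range(n_background)]
    genes = special + background

    base = rng.lognormal(mean=np.log(baseline_mean), sigma=0.4, size=n_genes)
    mu = np.tile(base, (n_cells, 1))
    gindex = {g: j for j, g in enumerate(genes)}
    sig_assign = rng.permutation(n_background)
    signature: dict[str, list[str]] = {}
    for i, p in enumerate(pops):
        cells = membership == i
        j = gindex[markers[p]]
        mu[:, j] = 0.0
        mu[cells, j] = marker_mean
        for g in decoys[p]:
            mu[cells, gindex[g]] *= decoy_fold
        start = i * signature_genes_per_population
        sig = sig_assign[start : start + signature_genes_per_population]
        signature[p] = [background[s] for s in sig]
        for s in sig:
            mu[cells, len(special) + s] *= signature_fold

    counts = _nb_counts(rng, mu, dispersion)
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    X = validate_expression(counts, cell_ids, genes, Orientation.CELLS_BY_GENES)
    keep = set(X.row_ids)
    labels = PopulationLabels(
        [c for c in cell_ids if c in keep],
        [pops[membership[i]] for i, c in enumerate(cell_ids) if c in keep],
    )
    return X, SingleCellTruth(labels, markers, decoys, signature)


# ---------------------------------------------------------------------------
# branching score-space trajectory


def _topology_nodes(topology: str) -> dict[str, np.ndarray]:
    """Polyline node coordinates per branch; branches share the trunk."""
    trunk = np.array([[-2.0, 0.0], [0.0, 0.0]])
    if topology == "bifurcating":
        return {
            "A": np.vstack([trunk, [[1.5, 1.2], [3.0, 2.4]]]),
            "B": np.vstack([trunk, [[1.5, -1.2], [3.0, -2.4]]]),
        }
    if topology == "chain":
        return {"A": np.vstack([trunk, [[2.0, 0.0], [4.0, 0.0]]])}
    raise ValueError(f"unknown topology {topology!r}")


def simulate_branching_scores(
    seed: int,
    n_cells: int = 600,
    topology: str = "bifurcating",
    noise_sd: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Cells scattered along a planted (possibly bifurcating) trajectory in a
    2D score space.

    Each cell is placed uniformly along one branch's polyline (branches share
    the trunk) plus isotropic Gaussian noise.  Returns
    (scores, latent arc position in [0,1], branch index per cell, branch names).
    """
    rng = np.random.default_rng(seed)
    nodes = _topology_nodes(topology)
    names = sorted(nodes)
    branch = rng.integers(0, len(names), size=n_cells)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    scores = np.zeros((n_cells, 2))
    for bi, name in enumerate(names):
        poly = nodes[name]
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        sel = branch == bi
        pos = t[sel] * total
        which = np.clip(np.searchsorted(cum, pos, side="right") - 1, 0, len(seg) - 1)
        frac = (pos - cum[which]) / seg[which]
        scores[sel] = poly[which] + frac[:, None] * (poly[which + 1] - poly[which])
    scores += rng.normal(0, noise_sd, scores.shape)
    return scores, t, branch, names
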