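"""Single-cell combinatorial CCA (SC4A).

Cells are the rows of the table and genes the columns, so the WA (row)
scores of each constrained solution are per-cell scores and the column
scores are per-gene scores.  The procedure has three steps:

1. a preliminary constrained ordination with per-cell covariates to reveal
   putative populations and candidate genes;
2. a pairwise tournament: for every unordered pair of candidate genes, a
   CCA is run with the pair's expression as covariates (the pair's columns
   removed from the main table) and, for each population, the gene whose
   biplot arrow subtends the smaller angle to the population centroid wins;
   genes are also scored by the F1 of a nearest-arrow classifier;
3. a final constrained solution using the winning gene of each population
   as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cca import CCASolution, cca
from .io import ExpressionMatrix, ExplanatoryMatrix, ValidationError

logger = logging.getLogger("sc4a")

MAX_CANDIDATES = 25  # exhaustive pairwise search guard


@dataclass
class PopulationLabels:
    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels length mismatch")

    @property
    def names(self) -> list[str]:
        return sorted(set(self.labels))

    def members(self, population: str) -> np.ndarray:
        return np.asarray([l == population for l in self.labels])

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="population")


@dataclass
class TournamentResult:
    """Aggregated pairwise-tournament records and per-population rankings."""

    records: pd.DataFrame  # population, gene, wins, n_pairings, mean_angle, mean_f1
    top_by_f1: dict[str, str]
    top_by_angle: dict[str, str]

    def select(self, prefer: str = "f1", manual: Mapping[str, str] | None = None) -> dict[str, str]:
        """One gene per population.

        Where the F1 and angle rankings agree the choice is forced; where
        they disagree, ``prefer`` ("f1" or "angle") resolves it, or a
        ``manual`` population->gene mapping overrides.
        """
        manual = dict(manual or {})
        out: dict[str, str] = {}
        for pop in self.top_by_f1:
            if pop in manual:
                out[pop] = manual[pop]
            elif self.top_by_f1[pop] == self.top_by_angle[pop]:
                out[pop] = self.top_by_f1[pop]
            elif prefer == "f1":
                out[pop] = self.top_by_f1[pop]
            elif prefer == "angle":
                out[pop] = self.top_by_angle[pop]
            else:
                raise ValueError(
                    f"rankings disagree for {pop!r} "
                    f"(f1: {self.top_by_f1[pop]}, angle: {self.top_by_angle[pop]}); "
                    "pass prefer='f1'|'angle' or a manual override"
                )
        return out

    @property
    def disagreements(self) -> list[str]:
        return [p for p in self.top_by_f1 if self.top_by_f1[p] != self.top_by_angle[p]]


def gene_variables(
    X: ExpressionMatrix, genes: Sequence[str]
) -> tuple[ExpressionMatrix, ExplanatoryMatrix]:
    """Split the table into covariates Z (the named genes' expression,
    standardized) and the remaining main table X' with those columns removed.

    Cells whose remaining row sum is zero are dropped from both sides so the
    two stay row-aligned.
    """
    missing = [g for g in genes if g not in X.col_ids]
    if missing:
        raise ValidationError(f"explanatory gene(s) absent from the matrix: {missing}")
    col_index = {g: i for i, g in enumerate(X.col_ids)}
    zcols = [col_index[g] for g in genes]
    zvals = X.values[:, zcols]
    rest = [i for i in range(X.m) if i not in set(zcols)]
    vals = X.values[:, rest]
    row_ok = vals.sum(axis=1) > 0
    col_ok = vals.sum(axis=0) > 0
    if not row_ok.all():
        logger.info("gene_variables: dropping %d cell(s) with zero remaining counts",
                    int((~row_ok).sum()))
    vals = vals[np.ix_(row_ok, col_ok)]
    Xp = ExpressionMatrix(
        vals,
        [r for r, k in zip(X.row_ids, row_ok) if k],
        [X.col_ids[i] for i, k in zip(rest, col_ok) if k],
        X.orientation,
    )
    Z = ExplanatoryMatrix(zvals[row_ok, :], list(genes)).standardize()
    return Xp, Z


def preliminary_cca(X: ExpressionMatrix, variables: ExplanatoryMatrix) -> CCASolution:
    """Step 1: constrained ordination of cells with per-cell covariates.

    ``variables`` must not duplicate a gene column still present in X (that
    would leak the covariate into the main table); derive gene-expression
    covariates through :func:`gene_variables` instead.
    """
    leaked = [n for n in variables.names if n in X.col_ids]
    if leaked:
        raise ValidationError(
            f"covariate gene(s) still present in the main table: {leaked}; "
            "use gene_variables() to remove them"
        )
    return cca(X, variables)


def cell_scores(solution: CCASolution) -> np.ndarray:
    """Per-cell score matrix of a cells-by-genes solution (row WA scores)."""
    return solution.gene_scores_wa


def cell_scores_principal(solution: CCASolution) -> np.ndarray:
    """Per-cell scores in principal scaling (axes weighted by alpha).

    Angle computations use this scaling so that near-degenerate axes, whose
    WA scores are inflated by the 1/alpha normalization, contribute in
    proportion to their actual share of the dispersion.
    """
    return solution.row_scores_principal


def gene_scores(solution: CCASolution) -> np.ndarray:
    """Per-gene score matrix of a cells-by-genes solution (column scores)."""
    return solution.sample_scores


def activation_scores_2d(solution: CCASolution, activation_variable: str) -> np.ndarray:
    """Axis-1 cell scores oriented so the named covariate points positive."""
    if activation_variable not in solution.var_names:
        raise ValidationError(f"unknown covariate {activation_variable!r}")
    idx = solution.var_names.index(activation_variable)
    sign = np.sign(solution.biplot[idx, 0]) or 1.0
    return cell_scores(solution)[:, 0] * sign


def define_populations(
    solution: CCASolution,
    marker: str,
    marker_values: np.ndarray | pd.Series,
    activation_variable: str | None = None,
) -> PopulationLabels:
    """Four-way labels from Axis-1 activation and marker positivity.

    Activated means a strictly positive oriented Axis-1 score (boundary cells
    fall to resting); marker-positive means strictly positive expression.
    """
    if isinstance(marker_values, pd.Series):
        marker_values = marker_values.reindex(solution.row_ids).to_numpy()
    marker_values = np.asarray(marker_values, dtype=float)
    if marker_values.shape[0] != len(solution.row_ids):
        raise ValidationError("marker_values length does not match the cells")
    if activation_variable is not None:
        act = activation_scores_2d(solution, activation_variable)
    else:
        act = cell_scores(solution)[:, 0]
    labels = [
        f"{'activated' if a > 0 else 'resting'}_{marker}{'pos' if v > 0 else 'neg'}"
        for a, v in zip(act, marker_values)
    ]
    return PopulationLabels(list(solution.row_ids), labels)


def candidate_genes(
    solution: CCASolution,
    populations: PopulationLabels,
    per_population: int = 5,
    override: Sequence[str] | None = None,
) -> list[str]:
    """Top candidate genes per population, ranked by the projection of each
    gene's score vector onto the population-centroid direction (alignment
    strength); deduplicated union.

    Plain cosine similarity is deliberately not used: near-zero noise genes
    whose direction happens to parallel the centroid would outrank strongly
    loaded population genes.  The projection weights alignment by loading.
    """
    if override is not None:
        known = set(solution.col_ids) | set(solution.var_names)
        missing = [g for g in override if g not in known]
        if missing:
            raise ValidationError(f"override gene(s) absent from the solution: {missing}")
        return list(override)
    if per_population < 1:
        raise ValueError("per_population must be >= 1")
    if populations.cell_ids != solution.row_ids:
        raise ValidationError("population labels and solution refer to different cells")
    cells = cell_scores_principal(solution)
    gvecs = gene_scores(solution)
    out: list[str] = []
    for pop in populations.names:
        centroid = cells[populations.members(pop)].mean(axis=0)
        cn = np.linalg.norm(centroid)
        if cn == 0:
            continue
        proj = gvecs @ (centroid / cn)
        order = np.argsort(-proj, kind="stable")
        for i in order[:per_population]:
            g = solution.col_ids[i]
            if g not in out:
                out.append(g)
    return out


def _angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.pi / 2  # undefined direction: orthogonal by convention
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def _f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int(np.sum(pred & truth))
    if tp == 0:
        return 0.0
    precision = tp / pred.sum()
    sensitivity = tp / truth.sum()
    return 2 * precision * sensitivity / (precision + sensitivity)


def combinatorial_cca(
    X: ExpressionMatrix,
    candidates: Sequence[str],
    populations: PopulationLabels,
) -> TournamentResult:
    """Step 2: exhaustive pairwise tournament over candidate genes.

    For each unordered candidate pair a two-covariate CCA is solved once;
    for each population (one vs rest) the pair's winner is the gene whose
    biplot arrow subtends the smaller angle to the population's centroid in
    the first two axes.  Each gene also receives an F1 score from the
    nearest-arrow classifier: a cell is predicted to belong to the target
    population iff its score vector is closer in angle to the gene's arrow
    than to the competitor's and its projection on that arrow is positive.
    """
    candidates = list(dict.fromkeys(candidates))
    if len(candidates) < 2:
        raise ValidationError("at least 2 candidate genes are required")
    if len(candidates) > MAX_CANDIDATES:
        raise ValidationError(
            f"{len(candidates)} candidates exceed the exhaustive-search guard "
            f"({MAX_CANDIDATES}); pre-select fewer candidates"
        )
    if len(populations.names) < 2:
        raise ValidationError("at least 2 populations are required")
    missing = [g for g in candidates if g not in X.col_ids]
    if missing:
        raise ValidationError(f"candidate gene(s) absent from the matrix: {missing}")

    pops = populations.names
    label_by_cell = dict(zip(populations.cell_ids, populations.labels))
    acc: dict[tuple[str, str], dict] = {
        (p, g): dict(wins=0, n=0, angles=[], f1s=[]) for p in pops for g in candidates
    }
    for g1, g2 in combinations(sorted(candidates), 2):
        Xp, Z = gene_variables(X, [g1, g2])
        sol = cca(Xp, Z)
        J2 = min(2, sol.J)
        if J2 == 0:
            continue
        arrows = {g: sol.biplot[i, :J2] * sol.alpha[:J2] for i, g in enumerate([g1, g2])}
        cells = cell_scores_principal(sol)[:, :J2]
        truth_all = np.asarray([label_by_cell[c] for c in sol.row_ids], dtype=object)
        # per-cell angle comparison is shared across populations
        cos = {}
        proj = {}
        for g in (g1, g2):
            a = arrows[g]
            na = np.linalg.norm(a)
            cn = np.linalg.norm(cells, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cos[g] = np.where(cn * na > 0, cells @ a / (cn * na), -1.0)
            proj[g] = cells @ a
        pred = {
            g1: (cos[g1] > cos[g2]) & (proj[g1] > 0),
            g2: (cos[g2] > cos[g1]) & (proj[g2] > 0),
        }
        for pop in pops:
            centroid = cells[truth_all == pop].mean(axis=0)
            ang = {g: _angle(arrows[g], centroid) for g in (g1, g2)}
            if np.isclose(ang[g1], ang[g2]):
                winner = min(g1, g2)
                logger.info("angle tie for %s between %s and %s; lexicographic break",
                            pop, g1, g2)
            else:
                winner = g1 if ang[g1] < ang[g2] else g2
            truth = truth_all == pop
            for g in (g1, g2):
                rec = acc[(pop, g)]
                rec["n"] += 1
                rec["angles"].append(ang[g])
                rec["f1s"].append(_f1(pred[g], truth))
                if g == winner:
                    rec["wins"] += 1

    rows = []
    for (pop, g), rec in acc.items():
        rows.append(dict(
            population=pop, gene=g, wins=rec["wins"], n_pairings=rec["n"],
            mean_angle=float(np.mean(rec["angles"])) if rec["angles"] else np.pi,
            mean_f1=float(np.mean(rec["f1s"])) if rec["f1s"] else 0.0,
        ))
    records = pd.DataFrame(rows)
    top_by_f1, top_by_angle = {}, {}
    for pop in pops:
        sub = records[records.population == pop]
        by_f1 = sub.sort_values(["mean_f1", "mean_angle", "gene"],
                                ascending=[False, True, True], kind="stable")
        by_angle = sub.sort_values(["mean_angle", "gene"],
                                   ascending=[True, True], kind="stable")
        top_by_f1[pop] = str(by_f1.iloc[0].gene)
        top_by_angle[pop] = str(by_angle.iloc[0].gene)
    return TournamentResult(records, top_by_f1, top_by_angle)


def final_sc4a(
    X: ExpressionMatrix, selected: Mapping[str, str] | Sequence[str]
) -> tuple[CCASolution, list[str]]:
    """Step 3: final constrained solution with the selected genes as
    covariates (their columns removed from the main table).

    Duplicate selections collapse with a warning (k is reduced).
    """
    genes = list(selected.values()) if isinstance(selected, Mapping) else list(selected)
    unique = list(dict.fromkeys(genes))
    if len(unique) < len(genes):
        logger.warning("duplicate selected genes collapsed: %d -> %d", len(genes), len(unique))
    Xp, Z = gene_variables(X, unique)
    return cca(Xp, Z), unique
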