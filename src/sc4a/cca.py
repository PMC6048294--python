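"""Correspondence analysis and canonically constrained CA (CCA).

The abundance table X (p rows x m columns, nonnegative) is converted to
chi-square standardized residuals

    P = X/n - r c^T,        S = Dr^{-1/2} P Dc^{-1/2},

whose squared Frobenius norm is the total inertia (the chi-square statistic
of the table divided by n).  Constrained CA projects S onto the column space
of the row covariates Z in the Dr metric,

    Q = Dr^{1/2} Z (Z^T Dr Z)^{-1} Z^T Dr^{1/2},    S* = Q S,

and decomposes S* = U Da V^T by SVD.  Eigenvalues are lambda_j = alpha_j^2
and the retained rank is J = min(p-1, m-1, k).  Column (sample) scores are
Dc^{-1/2} V Da — principal coordinates, so Euclidean distances between them
reproduce chi-square distances between column profiles.  Row scores are
weighted averages (WA scores) of the column scores,

    Gwa = Dr^{-1} P V Da^{-1}     (Dr^{-1} P V when k = 1),

and the biplot arrow of covariate z_n is its per-axis Pearson correlation
with u_j after Dr weighting.  With a single covariate the arrow degenerates
to +/-1, which orients the 1D "activation score".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, ExplanatoryMatrix, GeneSet, MassStructure, compute_masses

logger = logging.getLogger("sc4a")


@dataclass
class StandardizedResiduals:
    P: np.ndarray
    S: np.ndarray
    total_inertia: float


@dataclass
class ConstrainedSpace:
    basis: np.ndarray  # p x q orthonormal basis of the constrained subspace
    S_star: np.ndarray
    constrained_inertia: float

    def apply_Q(self, M: np.ndarray) -> np.ndarray:
        """Project M onto the constrained subspace (Q M)."""
        return self.basis @ (self.basis.T @ M)


@dataclass
class CCASolution:
    U: np.ndarray  # p x J left singular vectors
    V: np.ndarray  # m x J right singular vectors
    alpha: np.ndarray  # singular values, descending
    lam: np.ndarray  # eigenvalues alpha^2
    J: int
    sample_scores: np.ndarray  # m x J column principal coordinates
    gene_scores_wa: np.ndarray  # p x J row WA scores
    row_scores_principal: np.ndarray  # p x J, Dr^{-1} P V (alpha-weighted WA)
    biplot: np.ndarray  # k x J covariate-axis correlations
    inertia_fraction: np.ndarray
    total_inertia: float
    constrained_inertia: float
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    var_names: list[str] = field(default_factory=list)


def standardize(X: ExpressionMatrix, masses: MassStructure | None = None) -> StandardizedResiduals:
    """Chi-square standardized residuals of the table and its total inertia."""
    if masses is None:
        masses = compute_masses(X)
    r, c, n = masses.r, masses.c, masses.n
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("zero row/column mass; validate the matrix first")
    P = X.values / n - np.outer(r, c)
    S = P / np.outer(np.sqrt(r), np.sqrt(c))
    return StandardizedResiduals(P=P, S=S, total_inertia=float(np.sum(S * S)))


def project_constrained(
    resid: StandardizedResiduals,
    Z: ExplanatoryMatrix,
    masses: MassStructure,
) -> ConstrainedSpace:
    """Project S onto the Dr-weighted column space of Z.

    The regression carries an implicit intercept: Z is augmented with a
    constant column before weighting, exactly as a weighted least-squares
    fit of each column of S on Z would include one.  Because the rows of S
    are already centered in the Dr^{1/2} metric (S is orthogonal to
    Dr^{1/2} 1), the intercept direction absorbs nothing of S itself but
    makes the projector agree with plain CA when Z spans the full space.
    The projector is represented by an orthonormal basis of
    B = Dr^{1/2} [1 Z], obtained via a rank-revealing SVD; rank-deficient
    (collinear) Z triggers a warning and the projection falls back to the
    pseudo-inverse behaviour automatically.
    """
    if Z.k == 0:
        raise ValueError("at least one explanatory variable is required")
    if Z.Z.shape[0] != resid.S.shape[0]:
        raise ValueError(
            f"Z has {Z.Z.shape[0]} rows but the expression matrix has "
            f"{resid.S.shape[0]}; align the gene universes first"
        )
    p = Z.Z.shape[0]
    Zaug = np.column_stack([np.ones(p), Z.Z])
    B = np.sqrt(masses.r)[:, None] * Zaug
    # orthonormal basis of col(B); tolerance relative to the largest singular value
    Ub, sb, _ = np.linalg.svd(B, full_matrices=False)
    tol = 1e-10 * (sb[0] if sb.size else 0.0)
    rank = int(np.sum(sb > tol))
    if rank < min(Z.k + 1, p):
        logger.warning(
            "explanatory matrix is rank deficient (rank %d < k+1=%d); "
            "collinear directions dropped via pseudo-inverse", rank, Z.k + 1
        )
    T = Ub[:, :rank]
    S_star = T @ (T.T @ resid.S)
    return ConstrainedSpace(
        basis=T, S_star=S_star, constrained_inertia=float(np.sum(S_star * S_star))
    )


def _fix_signs(U: np.ndarray, V: np.ndarray) -> None:
    """Deterministic axis orientation: largest-|entry| of each u_j positive."""
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1


def decompose(
    space: ConstrainedSpace,
    resid: StandardizedResiduals,
    masses: MassStructure,
    k: int,
) -> CCASolution:
    """SVD of the constrained residuals; scores, eigenvalues, inertia shares.

    Retains J = min(p-1, m-1, k) axes.  The SVD is computed on the small
    matrix T^T S (rank of the projector), which is exact and fast when the
    number of covariates is far below min(p, m).
    """
    p, m = resid.S.shape
    J = max(0, min(p - 1, m - 1, k))
    small = space.basis.T @ resid.S  # q x m; S* = T @ small
    if small.size == 0 or not np.any(small):
        logger.warning("constrained space is all-zero; returning an empty solution")
        return CCASolution(
            U=np.zeros((p, 0)), V=np.zeros((m, 0)), alpha=np.zeros(0),
            lam=np.zeros(0), J=0,
            sample_scores=np.zeros((m, 0)), gene_scores_wa=np.zeros((p, 0)),
            row_scores_principal=np.zeros((p, 0)),
            biplot=np.zeros((0, 0)), inertia_fraction=np.zeros(0),
            total_inertia=resid.total_inertia, constrained_inertia=0.0,
        )
    Us, alpha, Vt = np.linalg.svd(small, full_matrices=False)
    U = space.basis @ Us
    V = Vt.T
    J = min(J, alpha.size)
    U, V, alpha = U[:, :J].copy(), V[:, :J].copy(), alpha[:J].copy()
    _fix_signs(U, V)
    lam = alpha**2
    inv_sqrt_c = 1.0 / np.sqrt(masses.c)
    sample_scores = inv_sqrt_c[:, None] * V * alpha[None, :]
    inv_r = 1.0 / masses.r
    row_scores_principal = inv_r[:, None] * (resid.P @ V)
    if k == 1:
        gene_scores_wa = row_scores_principal
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_alpha = np.where(alpha > 0, 1.0 / alpha, 0.0)
        gene_scores_wa = row_scores_principal * inv_alpha[None, :]
    lam_sum = lam.sum()
    frac = lam / lam_sum if lam_sum > 0 else np.zeros_like(lam)
    return CCASolution(
        U=U, V=V, alpha=alpha, lam=lam, J=J,
        sample_scores=sample_scores, gene_scores_wa=gene_scores_wa,
        row_scores_principal=row_scores_principal,
        biplot=np.zeros((0, J)), inertia_fraction=frac,
        total_inertia=resid.total_inertia,
        constrained_inertia=space.constrained_inertia,
    )


def biplot_correlations(
    Z: ExplanatoryMatrix, solution: CCASolution, masses: MassStructure
) -> np.ndarray:
    """Per-axis Dr-weighted Pearson correlations of the covariates with the
    ordination axes.

    The correlation is taken between z_n and the linear-combination row
    scores Dr^{-1/2} u_j under row-mass weights, which reduces to the cosine
    of u_j with d_n = Dr^{1/2} (z_n - mean_r(z_n)).  With a single covariate
    this is exactly +1 or -1 (the axis IS the covariate direction), which is
    what orients the 1D activation score.
    """
    if solution.J < 1:
        raise ValueError("solution has no axes")
    r = masses.r
    rho = np.zeros((Z.k, solution.J))
    for n in range(Z.k):
        z = Z.Z[:, n]
        d = np.sqrt(r) * (z - float(r @ z))
        nd = np.linalg.norm(d)
        if nd == 0:
            logger.warning(
                "weighted covariate %r is constant; biplot row set to 0",
                Z.names[n] if n < len(Z.names) else n,
            )
            continue
        for j in range(solution.J):
            u = solution.U[:, j]
            nu = np.linalg.norm(u)
            if nu == 0:
                continue
            rho[n, j] = float(d @ u / (nd * nu))
    return rho


def cca(X: ExpressionMatrix, Z: ExplanatoryMatrix) -> CCASolution:
    """Full constrained-CA pipeline: standardize, project, decompose, biplot.

    Z must be standardized (mean 0, variance 1 per column) and row-aligned
    with X.  Deterministic up to the documented axis-sign convention.
    """
    if not Z.standardized:
        Z = Z.standardize()
    masses = compute_masses(X)
    resid = standardize(X, masses)
    space = project_constrained(resid, Z, masses)
    sol = decompose(space, resid, masses, Z.k)
    if sol.J >= 1:
        sol.biplot = biplot_correlations(Z, sol, masses)
    else:
        sol.biplot = np.zeros((Z.k, 0))
    sol.row_ids = list(X.row_ids)
    sol.col_ids = list(X.col_ids)
    sol.var_names = list(Z.names)
    return sol


def activation_score(solution: CCASolution) -> np.ndarray:
    """Per-sample 1D activation score: Axis-1 sample score times the sign of
    the single biplot value, so high scores mean positive correlation with
    the explanatory signature regardless of its sign convention."""
    if solution.biplot.shape[0] != 1:
        raise ValueError(
            "activation_score requires a 1D solution (k=1); "
            "use per-axis sample scores for multi-variable solutions"
        )
    if solution.J == 0:
        return np.zeros(len(solution.col_ids))
    sign = np.sign(solution.biplot[0, 0])
    if sign == 0:
        sign = 1.0
    return solution.sample_scores[:, 0] * sign


def partition_gene_space(
    solution: CCASolution, axis1_quantile: float = 0.25
) -> dict[str, GeneSet]:
    """Fig-4A-style partition of the gene space.

    Genes in the lowest ``axis1_quantile`` of Axis-1 WA scores (the
    activation-correlated pole) form the activation set; these split by
    Axis-2 WA sign into a Foxp3-associated (Axis 2 >= 0) and a
    Runx1-associated (Axis 2 < 0) module.
    """
    if solution.J < 2:
        raise ValueError("gene-space partition requires at least 2 axes")
    g1 = solution.gene_scores_wa[:, 0]
    g2 = solution.gene_scores_wa[:, 1]
    thr = np.quantile(g1, axis1_quantile)
    tact_mask = g1 <= thr  # boundary ties included
    ids = np.asarray(solution.row_ids, dtype=object)
    tact = set(ids[tact_mask])
    foxp3 = set(ids[tact_mask & (g2 >= 0)])  # Axis-2 zero ties to the positive side
    runx1 = set(ids[tact_mask & (g2 < 0)])
    return {
        "tact": GeneSet("tact", tact),
        "tact_foxp3": GeneSet("tact_foxp3", foxp3) if foxp3 else _empty("tact_foxp3"),
        "tact_runx1": GeneSet("tact_runx1", runx1) if runx1 else _empty("tact_runx1"),
    }


def plot_biplot(solution: CCASolution, path: str, axes: tuple[int, int] = (0, 1)) -> None:
    """Write a 2D biplot (sample scores + covariate arrows) to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = axes
    if solution.J <= max(a, b):
        raise ValueError("solution has too few axes for the requested biplot")
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(solution.sample_scores[:, a], solution.sample_scores[:, b],
               s=12, c="0.4", alpha=0.7)
    scale = 0.9 * float(np.abs(solution.sample_scores[:, [a, b]]).max() or 1.0)
    for n, name in enumerate(solution.var_names):
        dx, dy = solution.biplot[n, a] * scale, solution.biplot[n, b] * scale
        ax.annotate("", xy=(dx, dy), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.text(dx, dy, name, color="tab:blue", fontsize=9)
    ax.axhline(0, lw=0.5, c="0.8")
    ax.axvline(0, lw=0.5, c="0.8")
    frac = solution.inertia_fraction
    ax.set_xlabel(f"Axis {a+1} ({100*frac[a]:.1f}%)")
    ax.set_ylabel(f"Axis {b+1} ({100*frac[b]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _empty(name: str) -> GeneSet:
    gs = GeneSet.__new__(GeneSet)
    gs.name = name
    gs.members = set()
    return gs
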