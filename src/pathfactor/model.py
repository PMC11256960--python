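"""Probabilistic core of the pathway factor model.

Observations of modality ``x`` (markers-by-samples matrix ``Y_x``) are
modelled as a pathway-constrained bilinear reconstruction with
heteroscedastic Gaussian noise::

    Y_x[m, n] ~ Normal( c_x * (C_x U B)[m, n] ,  sigma_x[m]^2 )

where ``C_x`` is the binary marker-by-pathway mask, ``U >= 0`` (pathways x
latents) carries the relevance of each pathway to each latent dimension,
``B`` (latents x samples) are the per-sample loadings, and ``c_x`` is a
modality-wide scalar absorbing normalization inconsistencies.  Entrywise
Gaussian priors ``U[p,k] ~ N(0, 1/Lambda[p,k])`` (automatic relevance
determination) and ``B[k,n] ~ N(0, 1/delta[k])`` regularize the parameters;
their precisions are hyperparameters optimized elsewhere via a Laplace
approximation to the marginal likelihood.

This module evaluates the negative log joint (the MAP objective), its
analytic gradients and blockwise Hessians, and the Laplace evidence.  The
Hessian of ``B`` is Kronecker-factored, ``H(B) = A_B (x) I_n`` with the
small ``k x k`` factor ``A_B``; only ``A_B`` is ever materialized.  The
Hessian of ``U`` is a dense ``pk x pk`` matrix (or its diagonal when the
diagonal approximation is requested).  With numpy's row-major ``ravel`` of
``U``, ``H(U) = sum_x c_x^2 (C_sigma^T C) (x) (B B^T) + diag(ravel(Lambda))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .genesets import PathwayMask

__all__ = [
    "ModalityData",
    "FactorModel",
    "HessianPair",
    "data_loglik",
    "neg_log_joint",
    "gradients",
    "hessians",
    "log_evidence",
]

# Default clamping bounds for ARD precisions and the noise-variance floor;
# pruned precisions diverge without the upper clamp.
PREC_MIN = 1e-6
PREC_MAX = 1e12
SIGMA_FLOOR = 1e-8


@dataclass
class ModalityData:
    """One modality's observations plus its noise and scale parameters."""

    Y: np.ndarray
    mask: PathwayMask
    sigma: np.ndarray | None = None  # per-marker noise std, defaults to ones
    scale: float = 1.0
    label: str = "rna"

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (markers x samples)")
        if self.Y.shape[0] != self.mask.n_markers:
            raise ValueError(
                f"{self.label}: Y has {self.Y.shape[0]} rows but mask covers "
                f"{self.mask.n_markers} markers"
            )
        if self.sigma is None:
            self.sigma = np.ones(self.Y.shape[0])
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.Y.shape[0],):
            raise ValueError(f"{self.label}: sigma length mismatch")
        if (self.sigma <= 0).any():
            raise ValueError(f"{self.label}: sigma must be strictly positive")
        if self.scale <= 0:
            raise ValueError(f"{self.label}: scale must be positive")

    @property
    def n_markers(self) -> int:
        return self.Y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]

    @property
    def C(self) -> np.ndarray:
        return self.mask.matrix

    @property
    def C_sigma(self) -> np.ndarray:
        """Mask with row ``m`` scaled by ``sigma_m^{-2}`` (precision-weighted)."""
        return self.mask.matrix / (self.sigma**2)[:, None]

    @property
    def weights(self) -> np.ndarray:
        """Per-marker observation precisions ``sigma^{-2}``."""
        return self.sigma**-2

    def project_weighted(self, X: np.ndarray) -> np.ndarray:
        """Compute ``C_sigma^T X`` through the sparse mask (p x n result)."""
        return self.mask.sparse.T @ (X * self.weights[:, None])

    def comembership_weighted(self) -> np.ndarray:
        """Dense ``C_sigma^T C`` (p x p precision-weighted co-membership)."""
        Csp = self.mask.sparse
        return (Csp.T @ Csp.multiply(self.weights[:, None])).toarray()

    def reconstruction(self, U: np.ndarray, B: np.ndarray) -> np.ndarray:
        return self.scale * (self.mask.sparse @ (U @ B))

    def residual(self, U: np.ndarray, B: np.ndarray) -> np.ndarray:
        return self.Y - self.reconstruction(U, B)


@dataclass
class FactorModel:
    """Parameters, hyperparameters and data of one factor-analysis problem."""

    U: np.ndarray
    B: np.ndarray
    Lambda: np.ndarray
    delta: np.ndarray
    modalities: list[ModalityData] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        p, k = self.U.shape
        if self.B.shape[0] != k:
            raise ValueError("U and B disagree on the latent dimension")
        if self.Lambda.shape != (p, k):
            raise ValueError("Lambda must match U's shape")
        if self.delta.shape != (k,):
            raise ValueError("delta must have one entry per latent")
        if (self.U < 0).any():
            raise ValueError("U must be non-negative")
        if (self.Lambda <= 0).any() or (self.delta <= 0).any():
            raise ValueError("prior precisions must be strictly positive")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        n = self.modalities[0].n_samples
        names = self.modalities[0].mask.pathway_names
        for mod in self.modalities:
            if mod.n_samples != n:
                raise ValueError("modalities disagree on the sample count")
            if mod.mask.pathway_names != names:
                raise ValueError("modalities must cover the same pathways, in order")
            if mod.mask.n_pathways != p:
                raise ValueError("mask pathway count inconsistent with U")
        if self.B.shape[1] != n:
            raise ValueError("B column count must equal the shared sample count")

    @property
    def n_pathways(self) -> int:
        return self.U.shape[0]

    @property
    def n_latents(self) -> int:
        return self.U.shape[1]

    @property
    def n_samples(self) -> int:
        return self.B.shape[1]

    def copy(self) -> "FactorModel":
        """Copy parameters and hyperparameters; Y and masks are shared
        (treated as immutable)."""
        return FactorModel(
            self.U.copy(),
            self.B.copy(),
            self.Lambda.copy(),
            self.delta.copy(),
            [
                ModalityData(m.Y, m.mask, m.sigma.copy(), m.scale, m.label)
                for m in self.modalities
            ],
        )


@dataclass
class HessianPair:
    """Blockwise Hessians of the MAP objective.

    ``H_U`` is the ``pk x pk`` Hessian with respect to ``ravel(U)`` (or its
    length-``pk`` diagonal when ``diagonal`` is set); ``A_B`` is the ``k x k``
    Kronecker factor of ``H(B) = A_B (x) I_n``.  Cholesky factorizations are
    computed lazily and cached, so the Newton solves, the fixed-point
    hyperparameter updates and the Laplace evidence all share one
    factorization per block.
    """

    H_U: np.ndarray
    A_B: np.ndarray
    diagonal: bool = False

    def chol_HU(self):
        if self.diagonal:
            raise ValueError("diagonal H_U has no Cholesky factor")
        if not hasattr(self, "_chol_HU"):
            try:
                self._chol_HU = linalg.cho_factor(self.H_U)
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError("H(U) is not positive-definite") from exc
        return self._chol_HU

    def chol_AB(self):
        if not hasattr(self, "_chol_AB"):
            try:
                self._chol_AB = linalg.cho_factor(self.A_B)
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError("A_B is not positive-definite") from exc
        return self._chol_AB

    def diag_HU_inv(self) -> np.ndarray:
        """Diagonal of ``H_U^{-1}`` (all the ARD update needs).

        From the Cholesky ``H = L L^T``: ``diag(H^{-1})`` is the column-wise
        squared norm of ``L^{-1}``, obtained by one triangular inversion.
        """
        if self.diagonal:
            return 1.0 / self.H_U
        c, lower = self.chol_HU()
        L_inv, info = linalg.lapack.dtrtri(c, lower=lower)
        if info != 0:
            raise linalg.LinAlgError("triangular inversion of H(U) failed")
        # cho_factor leaves junk in the unused triangle; dtrtri keeps it
        L_inv = np.tril(L_inv) if lower else np.triu(L_inv)
        return (L_inv**2).sum(axis=0 if lower else 1)

    def AB_inv(self) -> np.ndarray:
        return linalg.cho_solve(self.chol_AB(), np.eye(self.A_B.shape[0]))


def data_loglik(modality: ModalityData, U: np.ndarray, B: np.ndarray) -> float:
    """Gaussian log-likelihood of one modality's observations."""
    R = modality.residual(U, B)
    var = modality.sigma**2
    n = modality.n_samples
    quad = float(((R**2) / var[:, None]).sum())
    norm = n * float(np.log(2.0 * np.pi * var).sum())
    return -0.5 * (quad + norm)


def neg_log_joint(model: FactorModel) -> float:
    """MAP objective: minus log of (likelihoods x priors), constants included."""
    total = 0.0
    for mod in model.modalities:
        total -= data_loglik(mod, model.U, model.B)
    # -log p(U | Lambda), entrywise N(0, 1/Lambda)
    total += 0.5 * float(
        (model.Lambda * model.U**2).sum() - np.log(model.Lambda / (2.0 * np.pi)).sum()
    )
    # -log p(B | delta), row k has precision delta_k
    n = model.n_samples
    total += 0.5 * float(
        (model.delta[:, None] * model.B**2).sum()
        - n * np.log(model.delta / (2.0 * np.pi)).sum()
    )
    return total


def gradients(model: FactorModel) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the objective w.r.t. ``U`` and ``B``."""
    U, B = model.U, model.B
    G_U = model.Lambda * U
    G_B = model.delta[:, None] * B
    for mod in model.modalities:
        R = mod.residual(U, B)
        CsR = mod.project_weighted(R)  # p x n
        G_U -= mod.scale * (CsR @ B.T)
        G_B -= mod.scale * (U.T @ CsR)
    return G_U, G_B


def hessians(model: FactorModel, diagonal_U: bool = False) -> HessianPair:
    """Blockwise Hessians of the objective at the current parameters.

    Also the single place the fit loop obtains curvature: the ARD and noise
    hyperparameter updates reuse this pair, so each Hessian is formed at most
    once per iteration.
    """
    hessians.calls += 1
    U, B = model.U, model.B
    p, k = U.shape
    BBt = B @ B.T
    # All modalities share U and B, so their weighted co-membership matrices
    # sum into a single p x p Kronecker factor.
    S = np.zeros((p, p))
    for mod in model.modalities:
        S += mod.scale**2 * mod.comembership_weighted()
    A_B = U.T @ S @ U + np.diag(model.delta)
    if diagonal_U:
        H_U = model.Lambda.ravel() + np.outer(np.diag(S), np.diag(BBt)).ravel()
    else:
        H_U = (S[:, None, :, None] * BBt[None, :, None, :]).reshape(p * k, p * k)
        H_U[np.diag_indices(p * k)] += model.Lambda.ravel()
    return HessianPair(H_U, A_B, diagonal=diagonal_U)


hessians.calls = 0


def _logdet_from_cho(cho) -> float:
    return 2.0 * float(np.log(np.abs(np.diag(cho[0]))).sum())


def log_evidence(
    model: FactorModel,
    hessian_pair: HessianPair,
    objective: float | None = None,
) -> float:
    """Laplace approximation to the log marginal likelihood of (sigma, Lambda, delta).

    ``log p(Y | sigma, Lambda, delta) ~= log p(Y, U*, B*) - 1/2 log|H_U/(2 pi)|
    - 1/2 log|H_B/(2 pi)|`` with the ``B`` block reduced via
    ``log|A_B (x) I_n| = n log|A_B|``.  ``objective`` may carry a precomputed
    ``neg_log_joint(model)`` to avoid re-evaluating it.
    """
    p, k = model.U.shape
    n = model.n_samples
    if hessian_pair.diagonal:
        if (hessian_pair.H_U <= 0).any():
            raise linalg.LinAlgError("diagonal H_U has non-positive entries")
        logdet_HU = float(np.log(hessian_pair.H_U).sum())
    else:
        logdet_HU = _logdet_from_cho(hessian_pair.chol_HU())
    logdet_AB = _logdet_from_cho(hessian_pair.chol_AB())
    log_joint = -(neg_log_joint(model) if objective is None else objective)
    penalty = 0.5 * (logdet_HU - p * k * np.log(2.0 * np.pi)) + 0.5 * (
        n * logdet_AB - k * n * np.log(2.0 * np.pi)
    )
    return log_joint - penalty
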