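"""Bayesian alternating least-squares fit of the pathway factor model.

The MAP objective is quadratic in ``U`` at fixed ``B`` and vice versa, so a
Newton step with step size ``gamma <= 1`` on either block is an exact (or
damped) ridge solve and cannot increase the objective.  The fit loop
alternates these block updates, clamps ``U`` to the non-negative orthant,
and — using the very same Hessians — applies closed-form fixed-point updates
for all hyperparameters: the ARD precisions ``Lambda`` (entrywise on ``U``)
and ``delta`` (per latent on ``B``), the per-marker observation noises
``sigma``, and the per-modality scale factors.  Hyperparameter selection
therefore costs nothing beyond the ALS iteration itself.

Irrelevant entries are pruned automatically: when ``U[p,k]`` hits zero its
precision ``Lambda[p,k]`` is driven to the upper clamp ``prec_max`` and the
entry stays pinned; a latent whose loadings row collapses gets
``delta[k] = prec_max`` and is reported as pruned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .genesets import GeneSet, GeneSetCollection, PathwayMask, build_mask, read_gmt, write_gmt
from .model import (
    PREC_MAX,
    PREC_MIN,
    SIGMA_FLOOR,
    FactorModel,
    HessianPair,
    ModalityData,
    gradients,
    hessians,
    log_evidence,
    neg_log_joint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitReport",
    "update_B",
    "update_U",
    "update_hyperparameters",
    "update_scales",
    "fit",
    "infer_loadings",
    "save_model",
    "load_model",
]


@dataclass
class FitConfig:
    """Settings of the alternating least-squares fit.

    ``step_size`` is the Newton damping factor gamma in (0, 1]; 0.1 converges
    within tens to hundreds of iterations and is the recommended default.
    ``dof_mode`` selects the denominator of the noise-variance update:
    ``"sbl"`` uses the sparse-Bayesian-learning effective degrees of freedom
    ``n - k + tr(diag(delta) A_B^{-1})``; ``"as_printed"`` replaces ``k`` by
    the pathway count ``p``.  Both are clamped to at least 1 so the variance
    stays positive even when ``p > n``.
    """

    k: int = 10
    n_iter: int = 500
    step_size: float = 0.1
    seed: int = 0
    diagonal_U: bool = False
    prec_min: float = PREC_MIN
    prec_max: float = PREC_MAX
    sigma_floor: float = SIGMA_FLOOR
    init_precision_log_range: tuple[float, float] = (-4.0, 4.0)
    rel_tol: float = 1e-6
    dof_mode: str = "sbl"
    # First iterations run without hyperparameter updates so both parameter
    # blocks take a few damped steps before 1/U^2-style quantities are
    # trusted; 10 iterations = 5 steps per block.
    hyper_warmup: int = 10
    # Plumbing switches for ablation protocols; Algorithm defaults are True.
    update_hypers: bool = True
    update_scale_factors: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0.0 < self.step_size <= 1.0):
            raise ValueError("step_size must lie in (0, 1]")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if not (self.prec_min < self.prec_max):
            raise ValueError("prec_min must be smaller than prec_max")
        if self.dof_mode not in ("sbl", "as_printed"):
            raise ValueError(f"unknown dof_mode {self.dof_mode!r}")


@dataclass
class FitReport:
    """Per-iteration traces and convergence summary of one fit."""

    objective_trace: list[float] = field(default_factory=list)
    evidence_trace: list[float] = field(default_factory=list)
    pruned_latents: list[int] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def update_B(
    model: FactorModel,
    hessian_pair: HessianPair | None = None,
    step_size: float = 1.0,
) -> FactorModel:
    """Damped Newton step on the loadings ``B`` (in place on a copy).

    With ``step_size=1`` this is the exact ridge minimizer of the objective
    in ``B`` at fixed ``U``, solved through the small Kronecker factor
    ``A_B`` shared by every sample column.
    """
    if hessian_pair is None:
        hessian_pair = hessians(model)
    _, G_B = gradients(model)
    new = model.copy()
    new.B = model.B - step_size * linalg.cho_solve(hessian_pair.chol_AB(), G_B)
    return new


def update_U(
    model: FactorModel,
    hessian_pair: HessianPair | None = None,
    step_size: float = 1.0,
    prec_max: float = PREC_MAX,
) -> FactorModel:
    """Damped Newton step on ``U`` followed by projection onto ``U >= 0``.

    Entries whose ARD precision has reached ``prec_max`` are pruned: they are
    held at exactly zero rather than accumulating numerically negligible
    Newton dust.

    Projection after an unrestricted Newton step is not automatically
    monotone (curvature coupling can turn the clamped direction into ascent),
    so the step uses the two-metric projection scheme: the Newton solve is
    restricted to the free coordinates — entries that are interior, or at
    zero with a descending (negative) gradient — while bound coordinates
    whose gradient points outward stay at zero.  In the interior this is
    exactly the plain Newton step.  The objective restricted to ``U`` is
    quadratic with curvature ``H_U``, so the predicted change of the clamped
    candidate is ``g^T d + d^T H d / 2`` in closed form; if positive, the
    exact minimizer along the feasible segment to the candidate is taken,
    with a projected-gradient fallback when clamping annihilates the Newton
    direction entirely.  (Under the diagonal Hessian approximation the
    scheme is approximate, like the update itself.)
    """
    if hessian_pair is None:
        hessian_pair = hessians(model)
    G_U, _ = gradients(model)
    g = G_U.ravel()
    u = model.U.ravel()
    if hessian_pair.diagonal:
        if (hessian_pair.H_U <= 0).any():
            raise linalg.LinAlgError("diagonal H_U has non-positive entries")
        H_diag = hessian_pair.H_U
    else:
        H_diag = np.diag(hessian_pair.H_U)

    pinned = model.Lambda.ravel() >= prec_max
    active = ((u == 0.0) & (g >= 0.0)) | pinned
    free = ~active
    step = np.zeros_like(u)
    if free.any():
        if hessian_pair.diagonal:
            step[free] = g[free] / H_diag[free]
        elif free.all():
            step = linalg.cho_solve(hessian_pair.chol_HU(), g)
        else:
            H_ff = hessian_pair.H_U[np.ix_(free, free)]
            try:
                step[free] = linalg.cho_solve(linalg.cho_factor(H_ff), g[free])
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError(
                    "free-set block of H(U) is not positive-definite"
                ) from exc

    def clamp(candidate: np.ndarray) -> np.ndarray:
        candidate = np.maximum(candidate, 0.0)
        candidate[pinned] = 0.0
        return candidate

    def predicted_change(d: np.ndarray) -> tuple[float, float]:
        d1 = float(g @ d)
        if hessian_pair.diagonal:
            d2 = float(d @ (hessian_pair.H_U * d))
        else:
            d2 = float(d @ (hessian_pair.H_U @ d))
        return d1, d2

    cand = clamp(u - step_size * step)
    d = cand - u
    d1, d2 = predicted_change(d)
    if not d.any() or d1 >= 0.0:
        # Newton direction fully clamped away; fall back to a diagonally
        # preconditioned projected gradient step (always descends).
        fallback = np.zeros_like(u)
        fallback[free] = g[free] / H_diag[free]
        cand = clamp(u - step_size * fallback)
        d = cand - u
        d1, d2 = predicted_change(d)
    if d1 + 0.5 * d2 > 0.0 and d2 > 0.0:
        alpha = float(np.clip(-d1 / d2, 0.0, 1.0))
        cand = u + alpha * d

    new = model.copy()
    new.U = cand.reshape(model.U.shape)
    return new


def update_hyperparameters(
    model: FactorModel,
    hessian_pair: HessianPair,
    dof_mode: str = "sbl",
    prec_min: float = PREC_MIN,
    prec_max: float = PREC_MAX,
    sigma_floor: float = SIGMA_FLOOR,
) -> FactorModel:
    """Fixed-point updates of Lambda, delta and the per-marker noises.

    All three reuse the Hessians already computed for the ALS step.  The
    update for an ARD precision is ``(1 - prec * [H^{-1}]_diag) / param^2``;
    a parameter at zero sends its precision straight to ``prec_max`` (prune).
    Noise variances are the mean squared residual over an effective number of
    degrees of freedom (see ``FitConfig.dof_mode``), floored at
    ``sigma_floor``.
    """
    new = model.copy()
    U, B = model.U, model.B
    p, k = U.shape
    n = model.n_samples

    diag_HU_inv = hessian_pair.diag_HU_inv()
    AB_inv = hessian_pair.AB_inv()

    # Lambda: entrywise ARD on U.
    gamma_U = 1.0 - model.Lambda.ravel() * diag_HU_inv
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = gamma_U.reshape(p, k) / (U**2)
    lam[U == 0] = prec_max
    new.Lambda = np.clip(lam, prec_min, prec_max)

    # delta: per-latent ARD on B's rows.
    row_ss = (B**2).sum(axis=1)
    gamma_B = 1.0 - model.delta * np.diag(AB_inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlt = n * gamma_B / row_ss
    dlt[row_ss == 0] = prec_max
    new.delta = np.clip(dlt, prec_min, prec_max)

    # sigma: per-marker residual variance over effective degrees of freedom.
    trace = float(np.sum(model.delta * np.diag(AB_inv)))
    if dof_mode == "sbl":
        dof = n - k + trace
    else:  # "as_printed"
        dof = n - p + trace
    dof = max(dof, 1.0)
    for mod in new.modalities:
        rss = (mod.residual(U, B) ** 2).sum(axis=1)
        mod.sigma = np.sqrt(np.maximum(rss / dof, sigma_floor))
    return new


def update_scales(model: FactorModel) -> FactorModel:
    """Closed-form weighted least-squares update of each modality's scale.

    The scale minimizing the objective is the precision-weighted projection
    of ``Y`` on the unscaled reconstruction ``C U B``; an identically-zero
    reconstruction leaves the scale unchanged.
    """
    new = model.copy()
    for mod in new.modalities:
        R0 = mod.mask.sparse @ (model.U @ model.B)
        w = mod.weights[:, None]
        denom = float((w * R0 * R0).sum())
        if denom == 0.0:
            continue
        mod.scale = float((w * mod.Y * R0).sum()) / denom
        if mod.scale <= 0:
            # A non-positive projection would flip the reconstruction sign;
            # keep the scale at a tiny positive value instead.
            mod.scale = np.finfo(float).tiny
    return new


def _init_model(data: list[ModalityData], config: FitConfig) -> FactorModel:
    first = data[0]
    n = first.n_samples
    p = first.mask.n_pathways
    k = config.k
    if n < 1:
        raise ValueError("at least one sample is required")
    names = first.mask.pathway_names
    for mod in data[1:]:
        if mod.mask.pathway_names != names:
            raise ValueError("modalities must cover the same pathways, in order")
        if mod.n_samples != n:
            raise ValueError("modalities disagree on the sample count")
    if k > n or k > p:
        warnings.warn(
            f"k={k} exceeds the sample count ({n}) or pathway count ({p}); "
            "ARD will prune the surplus latents",
            stacklevel=3,
        )

    # B from the k-truncated SVD of the first modality, scaled by the
    # singular values so initial loadings carry the data's magnitude.  SVD
    # component signs are arbitrary, but the pathway weights are constrained
    # non-negative, so each component's reconstruction direction (its left
    # singular vector, which stands in for a non-negative combination C u)
    # is oriented to be predominantly positive; without this, a sign-flipped
    # latent cannot be represented and its share of signal is lost.
    left, s, Vt = np.linalg.svd(first.Y, full_matrices=False)
    r = min(k, s.size)
    flips = np.where(left[:, :r].sum(axis=0) < 0, -1.0, 1.0)
    B0 = np.zeros((k, n))
    B0[:r] = flips[:, None] * (s[:r, None] * Vt[:r])

    lo, hi = config.init_precision_log_range
    prec = np.logspace(lo, hi, k)
    Lambda0 = np.outer(np.ones(p), prec)
    modalities = [
        ModalityData(m.Y, m.mask, np.ones(m.n_markers), 1.0, m.label) for m in data
    ]
    return FactorModel(np.zeros((p, k)), B0, Lambda0, prec.copy(), modalities)


def fit(
    data: list[ModalityData] | ModalityData,
    config: FitConfig | None = None,
) -> tuple[FactorModel, FitReport]:
    """Run the full Bayesian ALS loop on one or two modalities.

    Iteration ``t`` updates ``U`` when ``t`` is odd and ``B`` when even (the
    loadings start from the truncated SVD, so pathway weights move first),
    then refreshes all hyperparameters and scale factors with the same
    Hessians.  Stops after ``n_iter`` iterations or when the relative change
    of the objective drops below ``rel_tol``.
    """
    if isinstance(data, ModalityData):
        data = [data]
    if not data:
        raise ValueError("at least one modality is required")
    config = config or FitConfig()
    model = _init_model(data, config)
    report = FitReport()

    prev_obj = neg_log_joint(model)
    for t in range(1, config.n_iter + 1):
        base = model
        hpair = hessians(model, diagonal_U=config.diagonal_U)
        if t % 2 == 1:
            model = update_U(model, hpair, config.step_size, config.prec_max)
        else:
            model = update_B(model, hpair, config.step_size)
        if config.update_hypers and t > config.hyper_warmup:
            # The fixed-point updates are derived at the MAP; with a damped
            # step size the iterate lags its Newton target, and evaluating
            # 1/U^2 (or 1/sum B^2) at the lagging iterate would prune viable
            # entries in the very first iterations.  Evaluate the updates at
            # the undamped Newton (MAP-proxy) candidate of both blocks —
            # built from this iteration's Hessians, identical to the iterate
            # at convergence.
            if config.step_size == 1.0:
                probe = model
            else:
                probe = update_U(base, hpair, 1.0, config.prec_max)
                probe = update_B(probe, hpair, 1.0)
            hyper = update_hyperparameters(
                probe,
                hpair,
                dof_mode=config.dof_mode,
                prec_min=config.prec_min,
                prec_max=config.prec_max,
                sigma_floor=config.sigma_floor,
            )
            new_Lambda = hyper.Lambda.copy()
            # Entries at zero in the proxy but pulled inward by the data
            # gradient are transiently clamped, not structurally dead: keep
            # their previous precision instead of pruning them.
            G_U_now, _ = gradients(model)
            transient = (probe.U == 0.0) & (G_U_now < 0.0)
            new_Lambda[transient] = model.Lambda[transient]
            model = model.copy()
            model.Lambda = new_Lambda
            model.delta = hyper.delta
            for mod, hyper_mod in zip(model.modalities, hyper.modalities):
                mod.sigma = hyper_mod.sigma
        if config.update_scale_factors:
            model = update_scales(model)
            # The likelihood is invariant under (scales*s, U/s): fix the
            # gauge by folding the geometric mean of the scales into U, so
            # the scales carry only the relative calibration between
            # modalities and the damped U iterate cannot ratchet it away.
            s = float(
                np.prod([mod.scale for mod in model.modalities])
            ) ** (1.0 / len(model.modalities))
            if s > 0.0 and s != 1.0:
                model.U = model.U * s
                for mod in model.modalities:
                    mod.scale /= s

        obj = neg_log_joint(model)
        report.objective_trace.append(obj)
        try:
            report.evidence_trace.append(log_evidence(model, hpair, obj))
        except linalg.LinAlgError:
            report.evidence_trace.append(float("nan"))
        report.iterations_run = t
        logger.debug(
            "iter %d: objective=%.6g evidence=%.6g pruned=%d",
            t,
            obj,
            report.evidence_trace[-1],
            int((model.delta >= config.prec_max).sum()),
        )
        if abs(obj - prev_obj) <= config.rel_tol * max(1.0, abs(prev_obj)):
            report.converged = True
            break
        prev_obj = obj

    report.pruned_latents = [
        int(i) for i in np.flatnonzero(model.delta >= config.prec_max)
    ]
    return model, report


def infer_loadings(
    model: FactorModel, new_data: list[ModalityData] | ModalityData
) -> np.ndarray:
    """Infer loadings for held-out samples with all model parameters frozen.

    Per test column the exact ridge solution
    ``A_B^{-1} (sum_x c_x U^T C_{x,sigma}^T y_x)`` — identical to one exact
    Newton step on ``B`` started from zero.
    """
    if isinstance(new_data, ModalityData):
        new_data = [new_data]
    if len(new_data) != len(model.modalities):
        raise ValueError("new_data must provide one entry per fitted modality")
    n_test = new_data[0].n_samples
    for new, ref in zip(new_data, model.modalities):
        if new.mask.marker_ids != ref.mask.marker_ids:
            raise ValueError(
                f"{ref.label}: marker universe of new data does not match the fit"
            )
        if new.n_samples != n_test:
            raise ValueError("test modalities disagree on the sample count")

    U = model.U
    A_B = np.diag(model.delta).astype(float)
    rhs = np.zeros((model.n_latents, n_test))
    for new, ref in zip(new_data, model.modalities):
        A_B += ref.scale**2 * (U.T @ ref.comembership_weighted() @ U)
        rhs += ref.scale * (U.T @ ref.project_weighted(new.Y))
    return linalg.cho_solve(linalg.cho_factor(A_B), rhs)


# ---------------------------------------------------------------------------
# Serialization: a fitted model as a directory of TSV matrices + JSON report.


def save_model(
    model: FactorModel,
    outdir: str | Path,
    report: FitReport | None = None,
    config: FitConfig | None = None,
    sample_ids: list[str] | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p, k = model.U.shape
    pathways = model.modalities[0].mask.pathway_names
    latents = [f"latent_{i}" for i in range(k)]
    samples = sample_ids or [f"sample_{j}" for j in range(model.n_samples)]

    pd.DataFrame(model.U, index=pathways, columns=latents).to_csv(
        outdir / "U.tsv", sep="\t", index_label="pathway"
    )
    pd.DataFrame(model.B, index=latents, columns=samples).to_csv(
        outdir / "B.tsv", sep="\t", index_label="latent"
    )
    pd.DataFrame(model.Lambda, index=pathways, columns=latents).to_csv(
        outdir / "Lambda.tsv", sep="\t", index_label="pathway"
    )
    pd.DataFrame({"delta": model.delta}, index=latents).to_csv(
        outdir / "delta.tsv", sep="\t", index_label="latent"
    )
    meta: dict = {"modalities": []}
    for mod in model.modalities:
        pd.DataFrame({"sigma": mod.sigma}, index=mod.mask.marker_ids).to_csv(
            outdir / f"sigma_{mod.label}.tsv", sep="\t", index_label="marker"
        )
        sets = [
            GeneSet(
                name,
                "",
                frozenset(
                    np.asarray(mod.mask.marker_ids)[mod.mask.matrix[:, j] == 1]
                ),
            )
            for j, name in enumerate(mod.mask.pathway_names)
        ]
        write_gmt(GeneSetCollection(sets), outdir / f"mask_{mod.label}.gmt")
        (outdir / f"markers_{mod.label}.txt").write_text(
            "\n".join(mod.mask.marker_ids) + "\n"
        )
        meta["modalities"].append({"label": mod.label, "scale": mod.scale})
    if report is not None:
        meta["report"] = asdict(report)
    if config is not None:
        meta["config"] = asdict(config)
    (outdir / "model.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(indir: str | Path) -> FactorModel:
    """Rebuild a fitted model from ``save_model`` output.

    Training observations are not serialized; the restored modalities carry
    zero-filled placeholders of the training width, which is sufficient for
    ``infer_loadings`` and held-out evaluation (both read only the fitted
    parameters and masks).
    """
    indir = Path(indir)
    U = pd.read_csv(indir / "U.tsv", sep="\t", index_col=0)
    B = pd.read_csv(indir / "B.tsv", sep="\t", index_col=0)
    Lambda = pd.read_csv(indir / "Lambda.tsv", sep="\t", index_col=0)
    delta = pd.read_csv(indir / "delta.tsv", sep="\t", index_col=0)["delta"]
    meta = json.loads((indir / "model.json").read_text())
    n_train = B.shape[1]
    modalities = []
    for entry in meta["modalities"]:
        label = entry["label"]
        markers = (indir / f"markers_{label}.txt").read_text().splitlines()
        collection = read_gmt(indir / f"mask_{label}.gmt")
        collection = GeneSetCollection(
            [next(s for s in collection if s.name == name) for name in U.index]
        )
        mask = build_mask(collection, markers)
        sigma = pd.read_csv(indir / f"sigma_{label}.tsv", sep="\t", index_col=0)
        modalities.append(
            ModalityData(
                np.zeros((len(markers), n_train)),
                mask,
                sigma.loc[markers, "sigma"].to_numpy(),
                entry["scale"],
                label,
            )
        )
    return FactorModel(
        U.to_numpy(), B.to_numpy(), Lambda.to_numpy(), delta.to_numpy(), modalities
    )
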