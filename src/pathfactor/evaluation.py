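"""Held-out evaluation and downstream association statistics.

Evaluation follows a fit-then-freeze protocol: the model is fitted on
training samples, frozen, loadings are inferred for held-out samples, and
the reconstruction is scored by its entrywise Gaussian log-density under the
model's own noise estimates.  With synthetic data the ground-truth model
provides the upper-bound reference for this score, and the quality of the
noise estimates is summarized by the mean absolute error against the true
per-marker standard deviations.

Downstream, samples are represented by pathway activities ``P = U B``
(pathways x samples); each pathway row can then be associated with a
continuous covariate (Pearson correlation with a t-transform p-value) or a
binary outcome label (Welch two-sample t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import FactorModel, ModalityData, data_loglik

__all__ = [
    "EvalResult",
    "PathwayActivities",
    "reconstruction_loglik",
    "noise_mae",
    "pathway_activities",
    "associate_continuous",
    "associate_binary",
    "rank_associations",
]


@dataclass
class EvalResult:
    recon_loglik: dict[str, float]
    noise_mae: dict[str, float]
    n_train: int
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, ll in self.recon_loglik.items():
            rows.append(
                {
                    "modality": label,
                    "recon_loglik": ll,
                    "noise_mae": self.noise_mae.get(label, np.nan),
                    "n_train": self.n_train,
                    "n_test": self.n_test,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PathwayActivities:
    """Per-sample pathway abundances ``P = U B``."""

    P: np.ndarray
    pathway_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.pathway_names), len(self.sample_ids)):
            raise ValueError("P shape inconsistent with its labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.pathway_names, columns=self.sample_ids)


def reconstruction_loglik(
    model: FactorModel,
    test_data: list[ModalityData] | ModalityData,
    B_test: np.ndarray,
) -> dict[str, float]:
    """Gaussian log-density of held-out observations under the (frozen) model.

    The supplied model may be a fitted one or the ground truth; its ``U``,
    noises and scales are used with the given test loadings.
    """
    if isinstance(test_data, ModalityData):
        test_data = [test_data]
    if len(test_data) != len(model.modalities):
        raise ValueError("test_data must provide one entry per model modality")
    out: dict[str, float] = {}
    for new, ref in zip(test_data, model.modalities):
        if new.Y.shape[0] != ref.n_markers:
            raise ValueError(f"{ref.label}: marker count mismatch")
        if new.Y.shape[1] != B_test.shape[1]:
            raise ValueError("B_test column count must match the test samples")
        scored = ModalityData(new.Y, ref.mask, ref.sigma, ref.scale, ref.label)
        out[ref.label] = data_loglik(scored, model.U, B_test)
    return out


def noise_mae(sigma_hat: np.ndarray, sigma_true: np.ndarray) -> float:
    """Mean absolute error of estimated vs true per-marker noise stds."""
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    sigma_true = np.asarray(sigma_true, dtype=float)
    if sigma_hat.shape != sigma_true.shape:
        raise ValueError("noise vectors must have equal length")
    return float(np.abs(sigma_hat - sigma_true).mean())


def pathway_activities(
    model: FactorModel | np.ndarray,
    B: np.ndarray,
    sample_ids: list[str] | None = None,
) -> PathwayActivities:
    """Project loadings into pathway space: ``P = U B``."""
    if isinstance(model, FactorModel):
        U = model.U
        names = model.modalities[0].mask.pathway_names
    else:
        U = np.asarray(model, dtype=float)
        names = [f"pathway_{i:02d}" for i in range(U.shape[0])]
    P = U @ B
    if sample_ids is None:
        sample_ids = [f"sample_{j:03d}" for j in range(P.shape[1])]
    return PathwayActivities(P, list(names), sample_ids)


def associate_continuous(
    activities: PathwayActivities,
    covariate: np.ndarray,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every pathway activity row with a covariate.

    Two-sided p-values come from the exact t-transform with n - 2 degrees of
    freedom.  Constant pathway rows have undefined correlation and are
    reported as 0 with ``constant=True``.  Set ``adjust`` for an extra
    Benjamini-Hochberg column.
    """
    covariate = np.asarray(covariate, dtype=float)
    n = covariate.size
    if n != len(activities.sample_ids):
        raise ValueError("covariate length must equal the sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")
    rows = []
    for name, row in zip(activities.pathway_names, activities.P):
        if np.ptp(row) == 0:
            rows.append({"pathway": name, "correlation": 0.0, "p_value": 1.0,
                         "constant": True})
        else:
            r, pval = stats.pearsonr(row, covariate)
            rows.append({"pathway": name, "correlation": float(r),
                         "p_value": float(pval), "constant": False})
    df = pd.DataFrame(rows)
    if adjust:
        df["p_adjusted"] = _bh_adjust(df["p_value"].to_numpy())
    return df


def associate_binary(
    activities: PathwayActivities,
    labels: np.ndarray,
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch two-sample t-test of every pathway activity row against a binary label."""
    labels = np.asarray(labels)
    if labels.size != len(activities.sample_ids):
        raise ValueError("labels length must equal the sample count")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("labels must take exactly two values")
    g0 = activities.P[:, labels == uniq[0]]
    g1 = activities.P[:, labels == uniq[1]]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    # Convention: positive t means the group with the larger label is higher.
    t, pval = stats.ttest_ind(g1, g0, axis=1, equal_var=False)
    df = pd.DataFrame(
        {
            "pathway": activities.pathway_names,
            "t_statistic": t,
            "p_value": pval,
        }
    )
    if adjust:
        df["p_adjusted"] = _bh_adjust(df["p_value"].to_numpy())
    return df


def rank_associations(df: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Order an association table by statistic magnitude, strongest first.

    Ties keep their original (first-index) order, which also serves as the
    tie-break when picking the single best-associated pathway.
    """
    if by is None:
        by = "correlation" if "correlation" in df.columns else "t_statistic"
    order = np.argsort(-df[by].abs().to_numpy(), kind="stable")
    return df.iloc[order].reset_index(drop=True)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]
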