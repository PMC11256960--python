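"""Synthetic two-modality benchmark with known pathway structure.

The generator emulates a matched transcriptomics + proteomics cohort in
which each of 50 pathways belongs to exactly one of 8 biological process
categories (development, DNA damage, immune, ...), and the categories act as
the ground-truth latent variables: ``U_true`` is the binary pathway-by-
category membership.  Samples fall into three clusters — loadings columns
are drawn from a mixture of three isotropic Gaussians whose means are
themselves Gaussian with a larger spread.  Marker-level observation noise is
heteroscedastic: per-marker standard deviations follow a moment-matched
log-normal with modality-specific mean and spread (RNA mean 0.95 with wider
spread, proteomics mean 0.98 with narrower spread), mirroring the noise
profiles seen in real matched tumor cohorts.

Pathway membership is simulated by sampling marker IDs per pathway from a
shared gene universe (overlaps allowed); the proteomics mask covers a
per-pathway subsample of the RNA markers relabelled through a generated
gene-to-protein mapping, mimicking the lower marker resolution of
mass-spectrometry proteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import (
    GeneSet,
    GeneSetCollection,
    PathwayMask,
    build_mask,
    write_gmt,
)
from .model import ModalityData
from .preprocess import ExpressionMatrix, write_matrix_tsv

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "draw_marker_noise",
    "simulate_truth",
    "simulate_dataset",
    "train_test_split",
    "write_dataset",
]


@dataclass
class SimConfig:
    """Benchmark settings; defaults are the study conditions."""

    p: int = 50
    k_true: int = 8
    n: int = 100
    markers_per_pathway: int = 200
    prot_fraction: float = 0.25
    n_genes: int | None = None  # gene universe size; default p*markers_per_pathway//2
    n_clusters: int = 3
    within_cluster_sd: float = 1.0
    cluster_mean_sd: float = 2.0
    noise_mean: dict = field(default_factory=lambda: {"rna": 0.95, "prot": 0.98})
    noise_spread: dict = field(default_factory=lambda: {"rna": 0.25, "prot": 0.10})
    scales: dict = field(default_factory=lambda: {"rna": 1.0, "prot": 1.0})
    weighted_U: bool = False  # scale memberships by positive draws (harder recovery)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < self.k_true:
            raise ValueError("need at least as many pathways as categories")
        if self.n < 1 or self.k_true < 1 or self.markers_per_pathway < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.prot_fraction <= 1):
            raise ValueError("prot_fraction must lie in (0, 1]")
        if self.within_cluster_sd <= 0 or self.cluster_mean_sd < 0:
            raise ValueError("cluster standard deviations must be positive")
        if any(v <= 0 for v in self.noise_mean.values()):
            raise ValueError("noise means must be positive")
        if any(v < 0 for v in self.noise_spread.values()):
            raise ValueError("noise spreads must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.n_genes or max(self.p * self.markers_per_pathway // 2, 1)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one simulated cohort."""

    U_true: np.ndarray
    B_true: np.ndarray
    cluster_labels: np.ndarray
    category_labels: np.ndarray
    sigma_true: dict[str, np.ndarray]
    masks: dict[str, PathwayMask]
    scales: dict[str, float]
    collections: dict[str, GeneSetCollection]
    mapping: list[tuple[str, str]]


def draw_marker_noise(
    m: int, mean: float, spread: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-marker noise std from a log-normal moment-matched to (mean, spread)."""
    if spread == 0:
        return np.full(m, mean)
    s2 = np.log1p((spread / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=m)


def _pathway_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_truth(config: SimConfig) -> SyntheticTruth:
    """Draw ground-truth structure: categories, masks, loadings, noises."""
    rng = _pathway_rng(config.seed, 0)
    p, k, n = config.p, config.k_true, config.n

    # Each pathway belongs to exactly one category, balanced then shuffled.
    category_labels = np.resize(np.arange(k), p)
    rng.shuffle(category_labels)
    U_true = np.zeros((p, k))
    U_true[np.arange(p), category_labels] = 1.0
    if config.weighted_U:
        U_true[np.arange(p), category_labels] = rng.uniform(0.5, 1.5, size=p)

    # RNA pathway membership over a shared gene universe; overlaps allowed.
    universe = [f"gene_{i:05d}" for i in range(config.universe_size)]
    n_draw = min(config.markers_per_pathway, len(universe))
    rna_sets, prot_sets, mapping_pairs = [], [], set()
    for j in range(p):
        genes = rng.choice(len(universe), size=n_draw, replace=False)
        members = [universe[g] for g in genes]
        rna_sets.append(GeneSet(f"pathway_{j:02d}", f"category_{category_labels[j]}",
                                frozenset(members)))
        n_prot = max(1, int(round(config.prot_fraction * n_draw)))
        sub = rng.choice(n_draw, size=n_prot, replace=False)
        prot_members = [f"prot_{members[i][5:]}" for i in sub]
        mapping_pairs.update((members[i], prot_members[idx]) for idx, i in enumerate(sub))
        prot_sets.append(GeneSet(f"pathway_{j:02d}", f"category_{category_labels[j]}",
                                 frozenset(prot_members)))
    collections = {
        "rna": GeneSetCollection(rna_sets),
        "prot": GeneSetCollection(prot_sets),
    }
    rna_markers = sorted(set().union(*(s.members for s in rna_sets)))
    prot_markers = sorted(set().union(*(s.members for s in prot_sets)))
    masks = {
        "rna": build_mask(collections["rna"], rna_markers),
        "prot": build_mask(collections["prot"], prot_markers),
    }

    # Loadings: mixture of isotropic Gaussians with Gaussian cluster means.
    cluster_labels = rng.integers(0, config.n_clusters, size=n)
    means = rng.normal(0.0, config.cluster_mean_sd, size=(k, config.n_clusters))
    B_true = means[:, cluster_labels] + rng.normal(
        0.0, config.within_cluster_sd, size=(k, n)
    )

    sigma_true = {
        label: draw_marker_noise(
            masks[label].n_markers,
            config.noise_mean[label],
            config.noise_spread[label],
            rng,
        )
        for label in ("rna", "prot")
    }
    return SyntheticTruth(
        U_true,
        B_true,
        cluster_labels,
        np.asarray(category_labels),
        sigma_true,
        masks,
        dict(config.scales),
        collections,
        sorted(mapping_pairs),
    )


def simulate_dataset(
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ModalityData]:
    """Observe the truth under heteroscedastic Gaussian noise.

    Returns ready-to-fit modalities: ``Y = scale * C U_true B_true + E`` with
    ``E[m, n] ~ Normal(0, sigma_true[m]^2)``.  The returned ``sigma`` fields
    are reset to ones (the fit estimates them); the truth stays separate.
    """
    if rng is None:
        rng = _pathway_rng(config.seed, 1)
    out = []
    for label in ("rna", "prot"):
        mask = truth.masks[label]
        clean = truth.scales[label] * (mask.matrix @ (truth.U_true @ truth.B_true))
        noise = rng.normal(0.0, 1.0, size=clean.shape) * truth.sigma_true[label][:, None]
        out.append(ModalityData(clean + noise, mask, None, 1.0, label))
    return out


def train_test_split(
    modalities: list[ModalityData], n_train: int
) -> tuple[list[ModalityData], list[ModalityData]]:
    """Split sample columns into disjoint train/test sets, masks shared."""
    n = modalities[0].n_samples
    if not (0 < n_train < n):
        raise ValueError(f"n_train must lie in (0, {n})")
    train = [
        ModalityData(m.Y[:, :n_train], m.mask, None, 1.0, m.label) for m in modalities
    ]
    test = [
        ModalityData(m.Y[:, n_train:], m.mask, None, 1.0, m.label) for m in modalities
    ]
    return train, test


def write_dataset(
    outdir: str | Path,
    modalities: list[ModalityData],
    truth: SyntheticTruth | None = None,
) -> None:
    """Write matrices, GMT masks and the gene-to-protein mapping to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = modalities[0].n_samples
    samples = [f"sample_{j:03d}" for j in range(n)]
    for mod in modalities:
        write_matrix_tsv(
            ExpressionMatrix(mod.Y, mod.mask.marker_ids, samples, stage="normalized"),
            outdir / f"{mod.label}.tsv",
        )
    if truth is not None:
        for label, coll in truth.collections.items():
            write_gmt(coll, outdir / f"{label}_sets.gmt")
        with open(outdir / "gene_to_protein.tsv", "w", encoding="utf-8") as fh:
            for src, tgt in truth.mapping:
                fh.write(f"{src}\t{tgt}\n")
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        pathways = truth.masks["rna"].pathway_names
        latents = [f"category_{i}" for i in range(truth.U_true.shape[1])]
        pd.DataFrame(truth.U_true, index=pathways, columns=latents).to_csv(
            tdir / "U_true.tsv", sep="\t", index_label="pathway"
        )
        pd.DataFrame(truth.B_true, index=latents, columns=samples).to_csv(
            tdir / "B_true.tsv", sep="\t", index_label="latent"
        )
        for label, sig in truth.sigma_true.items():
            pd.DataFrame(
                {"sigma_true": sig}, index=truth.masks[label].marker_ids
            ).to_csv(tdir / f"sigma_true_{label}.tsv", sep="\t", index_label="marker")
        pd.DataFrame(
            {"cluster": truth.cluster_labels}, index=samples
        ).to_csv(tdir / "clusters.tsv", sep="\t", index_label="sample")
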