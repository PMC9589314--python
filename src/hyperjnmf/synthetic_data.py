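"""Synthetic two-modality benchmark data.

The benchmark generator draws integer-uniform factors — W ~ U{1..10}
(n x K) and H_i ~ U{1..10} (K x p_i) — and emits X_i = W H_i + l * eta
with i.i.d. standard-normal noise eta scaled by the level l, clipped at 0
to preserve non-negativity (with factors >= 1 the noiseless product is at
least K, so clipping is negligible at the default levels). Defaults are
n = 100 samples, 100 features per modality, K = 45, with noise levels
{0, 1, 2, 5, 10} available for robustness sweeps. Diagnosis labels are
drawn 1/2 at a configurable prevalence, independent of the matrices.

A second, planted-structure generator lays out disjoint cross-modality
feature blocks, each loaded on its own factorization component, with known
ground-truth membership for recovery scoring (Jaccard overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DiagnosisVector, ModalityMatrix, ValidationError

__all__ = [
    "SyntheticConfig",
    "PlantedSpec",
    "SyntheticDataset",
    "DEFAULT_NOISE_LEVELS",
    "generate",
    "generate_planted",
    "jaccard",
]

DEFAULT_NOISE_LEVELS = (0.0, 1.0, 2.0, 5.0, 10.0)


@dataclass
class PlantedSpec:
    """Block structure for the planted-module generator."""

    n_blocks: int = 1
    block_size1: int = 10
    block_size2: int = 10
    block_low: float = 5.0  # member coefficient range in H
    block_high: float = 10.0
    background: float = 1.0  # upper bound of off-block coefficients


@dataclass
class SyntheticConfig:
    n_samples: int = 100
    p1: int = 100
    p2: int = 100
    K: int = 45
    noise_level: float = 0.0
    seed: int = 0
    label_prevalence: float = 0.5  # fraction of surgical (label 2) samples
    planted: PlantedSpec | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.p1 < 2 or self.p2 < 2:
            raise ValidationError("need at least 2 samples and 2 features per modality")
        if not 1 <= self.K <= self.n_samples:
            raise ValidationError("K must be in [1, n_samples]")
        if self.noise_level < 0:
            raise ValidationError("noise level must be non-negative")
        if not 0.0 < self.label_prevalence < 1.0:
            raise ValidationError("label_prevalence must be in (0, 1)")
        if self.planted is not None:
            ps = self.planted
            if ps.n_blocks > self.K:
                raise ValidationError("more planted blocks than components")
            if ps.n_blocks * ps.block_size1 > self.p1 or ps.n_blocks * ps.block_size2 > self.p2:
                raise ValidationError("planted blocks exceed the feature count")


@dataclass
class SyntheticDataset:
    x1: ModalityMatrix
    x2: ModalityMatrix
    true_W: np.ndarray
    true_H1: np.ndarray
    true_H2: np.ndarray
    labels: DiagnosisVector
    truth_members1: list[np.ndarray] = field(default_factory=list)
    truth_members2: list[np.ndarray] = field(default_factory=list)


def _labels(rng: np.random.Generator, n: int, prevalence: float) -> DiagnosisVector:
    lab = np.where(rng.random(n) < prevalence, 2, 1)
    # guarantee both classes are present
    if (lab == 1).all():
        lab[0] = 2
    elif (lab == 2).all():
        lab[0] = 1
    return DiagnosisVector(lab)


def _package(cfg: SyntheticConfig, w, h1, h2, rng) -> SyntheticDataset:
    x1 = w @ h1
    x2 = w @ h2
    if cfg.noise_level > 0:
        x1 = x1 + cfg.noise_level * rng.standard_normal(x1.shape)
        x2 = x2 + cfg.noise_level * rng.standard_normal(x2.shape)
    x1 = np.clip(x1, 0.0, None)
    x2 = np.clip(x2, 0.0, None)
    sample_ids = [f"s{i}" for i in range(cfg.n_samples)]
    m1 = ModalityMatrix(x1, sample_ids, [f"m1_f{j}" for j in range(cfg.p1)], "modality1")
    m2 = ModalityMatrix(x2, sample_ids, [f"m2_f{j}" for j in range(cfg.p2)], "modality2")
    labels = _labels(rng, cfg.n_samples, cfg.label_prevalence)
    labels.sample_ids = sample_ids
    return SyntheticDataset(m1, m2, w, h1, h2, labels)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Integer-uniform factor benchmark: X_i = W H_i + l * eta, clipped at 0."""
    if config.planted is not None:
        return generate_planted(config)
    rng = np.random.default_rng(config.seed)
    w = rng.integers(1, 11, size=(config.n_samples, config.K)).astype(float)
    h1 = rng.integers(1, 11, size=(config.K, config.p1)).astype(float)
    h2 = rng.integers(1, 11, size=(config.K, config.p2)).astype(float)
    return _package(config, w, h1, h2, rng)


def generate_planted(config: SyntheticConfig) -> SyntheticDataset:
    """Block-structured coefficients with known module membership.

    Block b occupies component b and the feature ranges
    [b*block_size, (b+1)*block_size) in each modality; member coefficients
    are drawn from U(block_low, block_high), everything else from
    U(0, background). The basis W stays integer-uniform. Ground-truth
    member index sets are returned for Jaccard scoring.
    """
    if config.planted is None:
        raise ValidationError("config.planted must be set")
    ps = config.planted
    rng = np.random.default_rng(config.seed)
    w = rng.integers(1, 11, size=(config.n_samples, config.K)).astype(float)
    h1 = rng.uniform(0.0, ps.background, size=(config.K, config.p1))
    h2 = rng.uniform(0.0, ps.background, size=(config.K, config.p2))

    truth1: list[np.ndarray] = []
    truth2: list[np.ndarray] = []
    for b in range(ps.n_blocks):
        idx1 = np.arange(b * ps.block_size1, (b + 1) * ps.block_size1)
        idx2 = np.arange(b * ps.block_size2, (b + 1) * ps.block_size2)
        h1[b, idx1] = rng.uniform(ps.block_low, ps.block_high, size=idx1.size)
        h2[b, idx2] = rng.uniform(ps.block_low, ps.block_high, size=idx2.size)
        truth1.append(idx1)
        truth2.append(idx2)

    ds = _package(config, w, h1, h2, rng)
    ds.truth_members1 = truth1
    ds.truth_members2 = truth2
    return ds


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two index sets; 1.0 when both are empty."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
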