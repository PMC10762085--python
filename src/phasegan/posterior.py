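"""Posterior sampling: ensembles, best-guess and uncertainty images.

Given a trained conditional generator and an incomplete sequence, the
missing phase is filled with the linear reconstructor and S latent draws
produce an ensemble of plausible complete sequences.  Pixel-wise empirical
statistics over the ensemble give the mean image (the best guess for the
missing phase) and the standard-deviation image (the confidence map).

The variance uses the population convention (divide by S): the SD image is
the plain ensemble average of (x - xbar)^2, square-rooted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .linear_recon import LinearModelSet, reconstruct
from .networks import Generator, sample_latent
from .phantom import IncompleteSequence

__all__ = [
    "Ensemble",
    "EnsembleStats",
    "DEFAULT_ENSEMBLE_SIZE",
    "sample_ensemble",
    "ensemble_statistic",
    "ensemble_stats",
    "impute",
]

#: Default number of generator draws per imputation.
DEFAULT_ENSEMBLE_SIZE = 800


@dataclass
class Ensemble:
    """S generated complete sequences conditioned on one filled sequence."""

    samples: np.ndarray  # [S, 4, H, W]
    conditioning: np.ndarray  # filled y, [4, H, W]
    missing_index: int
    seed: int

    def __post_init__(self):
        if self.samples.ndim != 4 or self.samples.shape[0] < 2:
            raise ValueError("ensemble needs at least 2 samples of shape [4,H,W]")
        if self.samples.shape[1:] != self.conditioning.shape:
            raise ValueError("samples and conditioning shapes disagree")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class EnsembleStats:
    mean: np.ndarray  # [4, H, W]
    sd: np.ndarray  # [4, H, W], population convention
    n_samples: int


def sample_ensemble(
    generator: Generator,
    incomplete: IncompleteSequence,
    models: LinearModelSet,
    n_samples: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    batch_size: int = 32,
) -> Ensemble:
    """Fill with R^j, then draw S = ``n_samples`` generator samples.

    Deterministic given ``seed``.  Samples are clipped to the normalized
    intensity domain [-1, 1] before any statistics are taken.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    filled = reconstruct(incomplete, models)
    y = filled.phases[None]  # [1, 4, H, W]
    rng = np.random.default_rng(seed)
    generator.eval()
    out = []
    done = 0
    while done < n_samples:
        b = min(batch_size, n_samples - done)
        z = sample_latent(rng, b, generator.spec.latent_dim)
        yb = np.broadcast_to(y, (b,) + y.shape[1:])
        xg = generator(yb, z).data
        out.append(np.clip(xg, -1.0, 1.0))
        done += b
    generator.train()
    return Ensemble(
        samples=np.concatenate(out, axis=0),
        conditioning=filled.phases.copy(),
        missing_index=incomplete.missing_index,
        seed=seed,
    )


def ensemble_statistic(
    ensemble: Ensemble, f: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Pixel-wise empirical mean of f over the ensemble: (1/S) sum f(x_i)."""
    vals = [np.asarray(f(s)) for s in ensemble.samples]
    first = vals[0].shape
    if any(v.shape != first for v in vals):
        raise ValueError("f must return equally shaped arrays for all samples")
    return np.mean(vals, axis=0)


def ensemble_stats(ensemble: Ensemble) -> EnsembleStats:
    """Mean and SD images via f(x) = x and f(x) = (x - xbar)^2."""
    mean = ensemble_statistic(ensemble, lambda s: s)
    var = ensemble_statistic(ensemble, lambda s: (s - mean) ** 2)
    return EnsembleStats(
        mean=mean, sd=np.sqrt(var), n_samples=ensemble.n_samples
    )


def impute(
    generator: Generator,
    incomplete: IncompleteSequence,
    models: LinearModelSet,
    n_samples: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, EnsembleStats]:
    """Best guess and confidence map for the missing phase.

    Returns ``(mean_j, sd_j, stats)`` where ``mean_j`` and ``sd_j`` are the
    mean and SD images of the missing phase j, extracted from the full
    4-phase ensemble statistics.
    """
    ens = sample_ensemble(generator, incomplete, models, n_samples, seed)
    stats = ensemble_stats(ens)
    j = incomplete.missing_index
    return stats.mean[j - 1], stats.sd[j - 1], stats
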