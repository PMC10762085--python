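"""Linear-regression initial guess for the missing phase.

Before the conditional generator sees an incomplete sequence, the missing
phase j is filled with the output of a linear reconstructor R^j.  Here R^j
is a pixel-shared affine map: a single intercept and one coefficient per
observed phase, fitted by ordinary least squares over all pixels of all
training subjects, with one model per possible missing index (four models
in total).  The filled value is clipped to the normalized intensity domain
[-1, 1]; observed phases are copied through bit-exactly.

The affine family is intentionally simple — the fill is only an initial
guess whose residual structure the generator learns to correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import N_PHASES, IncompleteSequence, PairedDataset

__all__ = [
    "FilledSequence",
    "LinearModel",
    "LinearModelSet",
    "fit_linear_models",
    "reconstruct",
    "fill_dataset",
    "save_models",
    "load_models",
]


@dataclass
class FilledSequence:
    """A 4-phase sequence whose slot ``filled_index`` holds a linear guess."""

    phases: np.ndarray  # [4, H, W]
    filled_index: int  # 1-based
    is_linear_guess: bool = True

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.phases.ndim != 3 or self.phases.shape[0] != N_PHASES:
            raise ValueError("phases must have shape [4, H, W]")
        if not 1 <= self.filled_index <= N_PHASES:
            raise ValueError("filled_index must be in 1..4")


@dataclass
class LinearModel:
    """Affine predictor of phase ``j`` from the three other phases."""

    j: int  # 1-based missing index
    intercept: float
    coefficients: np.ndarray  # one per observed phase, in observed order
    n_train_pairs: int = 0
    residual_variance: float = float("nan")

    def predict(self, observed: np.ndarray, clip: bool = True) -> np.ndarray:
        """Pixel-wise affine fill from observed phases [3, H, W]."""
        out = self.intercept + np.tensordot(self.coefficients, observed, axes=1)
        if clip:
            np.clip(out, -1.0, 1.0, out=out)
        return out


@dataclass
class LinearModelSet:
    """The four models R^1..R^4."""

    models: dict[int, LinearModel] = field(default_factory=dict)

    def __getitem__(self, j: int) -> LinearModel:
        if j not in self.models:
            raise KeyError(f"no linear model fitted for missing index {j}")
        return self.models[j]

    def __contains__(self, j: int) -> bool:
        return j in self.models


def fit_linear_models(train: PairedDataset) -> LinearModelSet:
    """Least-squares fit of x_j ~ a0 + sum_m a_m x_m for each j.

    The design matrix stacks every pixel of every training subject; the fit
    is solved with :func:`numpy.linalg.lstsq`.  A design whose observed
    phases are constant across the training set is singular and rejected.
    """
    seqs = train.complete_sequences()
    if not seqs:
        raise ValueError("training set is empty")
    stack = np.stack([s.phases for s in seqs])  # [K, 4, H, W]
    k = stack.shape[0]
    flat = stack.reshape(k, N_PHASES, -1)  # [K, 4, P]

    out = LinearModelSet()
    for j in range(1, N_PHASES + 1):
        obs_idx = [p for p in range(N_PHASES) if p != j - 1]
        target = flat[:, j - 1, :].ravel()
        design = np.column_stack(
            [np.ones(target.size)] + [flat[:, p, :].ravel() for p in obs_idx]
        )
        # a design is hopeless only if every observed phase is constant;
        # mere collinearity is handled by the least-squares minimum-norm fit
        if all(np.ptp(design[:, c]) < 1e-12 for c in range(1, design.shape[1])):
            raise np.linalg.LinAlgError(
                f"singular design for missing index {j}: all observed phases "
                "are constant across the training set"
            )
        coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ coef
        out.models[j] = LinearModel(
            j=j,
            intercept=float(coef[0]),
            coefficients=coef[1:].copy(),
            n_train_pairs=k,
            residual_variance=float(np.mean(resid**2)),
        )
    return out


def reconstruct(
    incomplete: IncompleteSequence, models: LinearModelSet
) -> FilledSequence:
    """Fill the missing slot with R^j; observed slots are copied bit-exactly."""
    j = incomplete.missing_index
    model = models[j]
    guess = model.predict(incomplete.observed)
    phases = np.empty((N_PHASES,) + incomplete.observed.shape[1:])
    for slot, p in enumerate(incomplete.observed_indices):
        phases[p - 1] = incomplete.observed[slot]
    phases[j - 1] = guess
    return FilledSequence(phases=phases, filled_index=j)


def fill_dataset(ds: PairedDataset, models: LinearModelSet) -> PairedDataset:
    """Populate the ``filled`` slot of every pair (in place; returns ds)."""
    for pair in ds.pairs:
        pair.filled = reconstruct(pair.incomplete, models)
    return ds


# -- serialization -------------------------------------------------------------


def save_models(models: LinearModelSet, path: str | Path) -> None:
    payload = {
        str(j): {
            "j": m.j,
            "intercept": m.intercept,
            "coefficients": list(m.coefficients),
            "n_train_pairs": m.n_train_pairs,
            "residual_variance": m.residual_variance,
        }
        for j, m in models.models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> LinearModelSet:
    payload = json.loads(Path(path).read_text())
    out = LinearModelSet()
    for j_str, m in payload.items():
        out.models[int(j_str)] = LinearModel(
            j=m["j"],
            intercept=m["intercept"],
            coefficients=np.asarray(m["coefficients"]),
            n_train_pairs=m["n_train_pairs"],
            residual_variance=m["residual_variance"],
        )
    return out
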