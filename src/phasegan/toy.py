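"""Jointly-Gaussian 1x1-"image" sanity problem with closed-form posterior.

Treats a 4-vector x ~ N(0, Sigma) as a 4-phase sequence of 1x1 images, so
the whole imputation pipeline (decimation, linear fill, conditional GAN,
ensemble statistics) can run unchanged on a problem whose conditional mean
and standard deviation are known exactly.  For a multivariate Gaussian the
conditional of the missing component given the other three is Gaussian with

    mean = Sigma_mo Sigma_oo^{-1} x_obs,    var = Sigma_mm - Sigma_mo Sigma_oo^{-1} Sigma_om

which is the oracle the trained generator's ensemble is checked against.

Intensities use sd 0.2 so the values live comfortably inside the
normalized domain [-1, 1] (clipping at 5 sigma is negligible).
"""

from __future__ import annotations

import numpy as np

from .phantom import ImputationPair, IncompleteSequence, PairedDataset, PhaseSequence, decimate

__all__ = ["TOY_COV", "make_toy_dataset", "conditional_moments"]

_SD = 0.2
_CORR = np.array(
    [
        [1.0, 0.7, 0.5, 0.3],
        [0.7, 1.0, 0.7, 0.5],
        [0.5, 0.7, 1.0, 0.7],
        [0.3, 0.5, 0.7, 1.0],
    ]
)
#: Covariance of the 4-phase toy vector.
TOY_COV = _SD**2 * _CORR


def make_toy_dataset(
    n_subjects: int,
    seed: int = 0,
    missing_only: int | None = None,
) -> PairedDataset:
    """Draw subjects from N(0, TOY_COV) as 1x1 4-phase sequences.

    ``missing_only`` restricts pairs to a single decimation index; by
    default all four decimations are built per subject.
    """
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(4), TOY_COV, size=n_subjects)
    x = np.clip(x, -1.0, 1.0)
    ds = PairedDataset()
    for i in range(n_subjects):
        seq = PhaseSequence(
            x[i].reshape(4, 1, 1), normalized=True, subject_id=f"T{i:05d}"
        )
        js = (missing_only,) if missing_only else (1, 2, 3, 4)
        for j in js:
            ds.pairs.append(ImputationPair(x=seq, incomplete=decimate(seq, j)))
    return ds


def conditional_moments(
    incomplete: IncompleteSequence,
) -> tuple[float, float]:
    """Analytic conditional mean and SD of the missing component."""
    j = incomplete.missing_index - 1
    obs_idx = [i for i in range(4) if i != j]
    s_oo = TOY_COV[np.ix_(obs_idx, obs_idx)]
    s_mo = TOY_COV[j, obs_idx]
    w = np.linalg.solve(s_oo, s_mo)
    x_obs = incomplete.observed[:, 0, 0]
    mean = float(w @ x_obs)
    var = float(TOY_COV[j, j] - s_mo @ w)
    return mean, float(np.sqrt(var))
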