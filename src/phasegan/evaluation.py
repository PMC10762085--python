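"""Image-fidelity metrics and the total-SD acceptability screen.

Metrics per imputed phase:

* NMSE — ||x_true - x_hat||^2 / ||x_true||^2 (squared-error normalized by
  the reference's squared norm; a mean-subtracted variant is available);
* SSIM — mean local structural similarity with an 11x11 Gaussian window
  (sigma 1.5), K1 = 0.01, K2 = 0.03, data range 2.0 for intensities in
  [-1, 1] (delegates to scikit-image);
* PSNR — 10 log10(data_range^2 / MSE), infinite for identical images.

For acceptability screening, an imputation is labelled "acceptable" when
its NMSE is at or below a threshold (default 0.1), and the total SD (the
SD image summed over pixels) is scored as a classifier of that label: low
total SD predicts acceptable.  The ROC uses "acceptable" as the positive
class with -total_sd as the score; the AUC equals the Mann-Whitney
statistic under the trapezoidal convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .linear_recon import LinearModelSet, reconstruct
from .networks import Generator
from .phantom import PHASE_NAMES, PairedDataset
from .posterior import impute

__all__ = [
    "MetricRecord",
    "ROCResult",
    "NMSE_THRESHOLD",
    "nmse",
    "ssim",
    "psnr",
    "acceptability_labels",
    "roc_auc",
    "evaluate_test_set",
    "evaluate_deterministic",
    "summary_table",
    "comparison_table",
]

#: Default acceptability threshold on NMSE.
NMSE_THRESHOLD = 0.1

#: Data range of normalized intensities in [-1, 1].
DATA_RANGE = 2.0


@dataclass
class MetricRecord:
    """Per-(subject, missing phase) metrics for one imputation."""

    subject_id: str
    missing_index: int
    nmse: float
    ssim: float
    psnr: float
    total_sd: float
    acceptable: bool | None = None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# -- metrics -------------------------------------------------------------------


def nmse(x_true: np.ndarray, x_hat: np.ndarray, mean_subtracted: bool = False) -> float:
    """Normalized mean squared error ||x_true - x_hat||^2 / ||x_true||^2."""
    x_true = np.asarray(x_true, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x_true.shape != x_hat.shape:
        raise ValueError("images must share shape")
    ref = x_true - x_true.mean() if mean_subtracted else x_true
    denom = np.sum(ref**2)
    if denom == 0:
        raise ValueError("reference image has zero norm")
    return float(np.sum((x_true - x_hat) ** 2) / denom)


def ssim(x_true: np.ndarray, x_hat: np.ndarray, data_range: float = DATA_RANGE) -> float:
    """Mean local SSIM, Gaussian 11x11 window (sigma 1.5), K1/K2 = 0.01/0.03."""
    x_true = np.asarray(x_true, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x_true.shape != x_hat.shape:
        raise ValueError("images must share shape")
    if min(x_true.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            x_true,
            x_hat,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def psnr(x_true: np.ndarray, x_hat: np.ndarray, data_range: float = DATA_RANGE) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    x_true = np.asarray(x_true, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x_true.shape != x_hat.shape:
        raise ValueError("images must share shape")
    mse = float(np.mean((x_true - x_hat) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


# -- acceptability screening ---------------------------------------------------


def acceptability_labels(
    records: list[MetricRecord], threshold: float = NMSE_THRESHOLD
) -> np.ndarray:
    """acceptable <=> NMSE <= threshold (inclusive bound); sets the flag too."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = np.array([r.nmse <= threshold for r in records], dtype=bool)
    for r, lab in zip(records, labels):
        r.acceptable = bool(lab)
    return labels


def roc_auc(total_sd: np.ndarray, acceptable: np.ndarray) -> ROCResult:
    """ROC of total SD as a screen for acceptability.

    "Acceptable" is the positive class; the score is -total_sd so that a low
    uncertainty predicts an acceptable imputation.
    """
    total_sd = np.asarray(total_sd, dtype=np.float64)
    acceptable = np.asarray(acceptable, dtype=bool)
    if total_sd.shape != acceptable.shape:
        raise ValueError("scores and labels must align")
    if acceptable.all() or (~acceptable).all():
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, thr = _roc_curve(acceptable.astype(int), -total_sd, pos_label=1)
    return ROCResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr))
    )


# -- test-set evaluation -------------------------------------------------------


def evaluate_test_set(
    generator: Generator,
    test: PairedDataset,
    models: LinearModelSet,
    n_samples: int = 50,
    seed: int = 0,
    threshold: float = NMSE_THRESHOLD,
) -> tuple[list[MetricRecord], pd.DataFrame, ROCResult | None]:
    """One record per (subject, missing phase); summary table; total-SD ROC.

    The ROC is ``None`` when every imputation falls into a single
    acceptability class (the AUC is undefined there).
    """
    records: list[MetricRecord] = []
    ss = np.random.SeedSequence(seed)
    for pair, child in zip(test.pairs, ss.spawn(len(test.pairs))):
        j = pair.incomplete.missing_index
        truth = pair.x.phases[j - 1]
        mean_j, sd_j, _ = impute(
            generator,
            pair.incomplete,
            models,
            n_samples=n_samples,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        records.append(
            MetricRecord(
                subject_id=pair.x.subject_id,
                missing_index=j,
                nmse=nmse(truth, mean_j),
                ssim=ssim(truth, mean_j),
                psnr=psnr(truth, mean_j),
                total_sd=float(sd_j.sum()),
            )
        )
    labels = acceptability_labels(records, threshold)
    table = summary_table(records)
    if labels.all() or (~labels).all():
        roc = None
    else:
        roc = roc_auc(np.array([r.total_sd for r in records]), labels)
    return records, table, roc


def evaluate_deterministic(
    predict,
    test: PairedDataset,
) -> list[MetricRecord]:
    """Evaluate a deterministic imputer ``predict(incomplete) -> [H, W]``.

    Used for the pix2pix baseline and the raw linear reconstructor; the
    total SD of a deterministic imputation is identically zero.
    """
    records = []
    for pair in test.pairs:
        j = pair.incomplete.missing_index
        truth = pair.x.phases[j - 1]
        guess = predict(pair.incomplete)
        records.append(
            MetricRecord(
                subject_id=pair.x.subject_id,
                missing_index=j,
                nmse=nmse(truth, guess),
                ssim=ssim(truth, guess),
                psnr=psnr(truth, guess),
                total_sd=0.0,
            )
        )
    return records


def linear_predictor(models: LinearModelSet):
    """Deterministic imputer that returns the bare linear fill."""

    def predict(incomplete):
        filled = reconstruct(incomplete, models)
        return filled.phases[incomplete.missing_index - 1]

    return predict


def pix2pix_predictor(generator: Generator, models: LinearModelSet):
    """Deterministic imputer running the pix2pix generator once."""

    def predict(incomplete):
        filled = reconstruct(incomplete, models)
        generator.eval()
        out = generator(filled.phases[None]).data[0]
        generator.train()
        return np.clip(out[incomplete.missing_index - 1], -1.0, 1.0)

    return predict


def summary_table(records: list[MetricRecord]) -> pd.DataFrame:
    """Per-phase and combined mean (SD across records) of each metric."""
    df = pd.DataFrame(
        {
            "phase": [PHASE_NAMES[r.missing_index - 1] for r in records],
            "nmse": [r.nmse for r in records],
            "ssim": [r.ssim for r in records],
            "psnr": [r.psnr for r in records],
        }
    )
    rows = {}
    for metric in ("ssim", "psnr", "nmse"):
        per_phase = df.groupby("phase", sort=False)[metric].mean()
        row = {name: per_phase.get(name, np.nan) for name in PHASE_NAMES}
        row["combined"] = df[metric].mean()
        row["combined_sd"] = df[metric].std(ddof=0)
        rows[metric] = row
    return pd.DataFrame(rows).T


def comparison_table(method_records: dict[str, list[MetricRecord]]) -> pd.DataFrame:
    """Stack per-method summaries into one table (methods as a row level)."""
    frames = []
    for method, recs in method_records.items():
        t = summary_table(recs)
        t.insert(0, "method", method)
        frames.append(t)
    out = pd.concat(frames)
    out.index.name = "metric"
    return out.reset_index().set_index(["metric", "method"]).sort_index()
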