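"""Synthetic four-phase contrast-enhanced CT phantoms.

Real renal CECT cohorts are not redistributable, so this module generates
2-D phantoms with the statistical structure the imputation method assumes:
each subject is a set of nested elliptical compartments (abdominal soft
tissue, renal cortex, medulla, pelvis/calyx, and a tumor of one of three
radiological types) whose intensities follow distinct enhancement curves
across the four acquisition phases (pre-contrast, corticomedullary,
nephrographic, excretory), on a pseudo-Hounsfield scale with additive
Gaussian noise.

Two sources of across-subject variability are built in deliberately:

* per-subject multiplicative contrast-amplitude factors for each
  post-contrast phase (emulating injection-timing and dose variability),
  which make some phases genuinely ambiguous given the others — the
  low-dimensional uncertainty a conditional generative model should spread
  its posterior over; and
* a per-subject noise level spanning standard-dose to very noisy
  acquisitions, giving a difficulty mix in which imputations fall on both
  sides of a fixed accuracy threshold.

The module also implements the preprocessing used downstream: clipping to
[-150, 1000] HU and affine mapping to [-1, 1], rotation/shift augmentation
(at most 11 variants per sequence), decimation of one phase, and subject-
disjoint train/validation/test dataset construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "Compartment",
    "PhantomSpec",
    "PhaseSequence",
    "IncompleteSequence",
    "ImputationPair",
    "PairedDataset",
    "PHASE_NAMES",
    "HU_RANGE",
    "CLIP_RANGE",
    "TUMOR_TYPES",
    "generate_phantom",
    "compartment_mask",
    "normalize",
    "denormalize",
    "augment",
    "decimate",
    "sample_spec",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

PHASE_NAMES = ("pre-contrast", "corticomedullary", "nephrographic", "excretory")
N_PHASES = 4

#: Full pseudo-Hounsfield range of the raw data.
HU_RANGE = (-3024.0, 3071.0)
#: Clip window applied before normalization to [-1, 1].
CLIP_RANGE = (-150.0, 1000.0)

TUMOR_TYPES = ("solid-enhancing", "fat-density", "cystic-septated")

# Baseline enhancement curves in pseudo-HU, one value per phase.  Cortex peaks
# in the corticomedullary phase, medulla in the nephrographic phase, and the
# collecting system (pelvis/calyx) fills with excreted contrast in the
# excretory phase.  Fat-density tumors sit near -95 HU at every phase;
# cystic tumors stay fluid-dense with enhancing septations.
BASE_CURVES: dict[str, tuple[float, float, float, float]] = {
    "soft-tissue": (35.0, 60.0, 70.0, 65.0),
    "cortex": (32.0, 185.0, 135.0, 100.0),
    "medulla": (30.0, 60.0, 135.0, 100.0),
    "pelvis": (10.0, 18.0, 40.0, 330.0),
    "solid-enhancing": (33.0, 115.0, 90.0, 75.0),
    "fat-density": (-95.0, -92.0, -93.0, -92.0),
    "cystic-fluid": (12.0, 16.0, 20.0, 22.0),
    "septum": (30.0, 90.0, 75.0, 60.0),
}

# SD of the log contrast-amplitude factor per post-contrast phase.  The
# corticomedullary and excretory phases are the most timing-sensitive.
AMPLITUDE_SD = {2: 0.20, 3: 0.12, 4: 0.30}
AMPLITUDE_SHARED_SD = 0.10
ENHANCEMENT_JITTER_SD = 10.0  # additive per-compartment, per-phase, pseudo-HU

#: Per-subject noise SD range (pseudo-HU): standard-dose to very noisy.  The
#: upper end puts the NMSE noise floor of the noisiest subjects well above
#: the 0.1 acceptability threshold, so a cohort always contains clearly
#: unacceptable imputations alongside easy ones.
NOISE_SD_RANGE = (20.0, 160.0)


@dataclass(frozen=True)
class Compartment:
    """An ellipse with one enhancement value per phase.

    Compartments are painted in list order, so later (inner) compartments
    overwrite earlier ones.
    """

    name: str
    center: tuple[float, float]  # (row, col) in pixels
    axes: tuple[float, float]  # (row, col) semi-axes in pixels
    angle: float  # rotation in degrees
    enhancement: tuple[float, float, float, float]  # pseudo-HU per phase


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, enhancement and noise description of one synthetic subject."""

    image_size: int
    compartments: tuple[Compartment, ...]
    tumor_type: str
    noise_sd: float
    seed: int

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tumor_type not in TUMOR_TYPES:
            raise ValueError(f"unknown tumor type {self.tumor_type!r}")
        if not self.compartments:
            raise ValueError("at least one compartment is required")
        lo, hi = HU_RANGE
        for comp in self.compartments:
            if len(comp.enhancement) != N_PHASES:
                raise ValueError("enhancement must have one value per phase")
            if not all(lo <= e <= hi for e in comp.enhancement):
                raise ValueError(
                    f"enhancement of {comp.name!r} outside pseudo-HU range {HU_RANGE}"
                )


@dataclass
class PhaseSequence:
    """Four co-registered phase images of one subject."""

    phases: np.ndarray  # [4, H, W]
    normalized: bool
    subject_id: str

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.phases.ndim != 3 or self.phases.shape[0] != N_PHASES:
            raise ValueError("phases must have shape [4, H, W]")
        if self.normalized:
            lo, hi = self.phases.min(), self.phases.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError("normalized intensities must lie in [-1, 1]")


@dataclass
class IncompleteSequence:
    """Three observed phases; phase ``missing_index`` (1-based) is absent."""

    observed: np.ndarray  # [3, H, W]
    missing_index: int
    subject_id: str

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=np.float64)
        if self.observed.ndim != 3 or self.observed.shape[0] != N_PHASES - 1:
            raise ValueError("observed must have shape [3, H, W]")
        if not 1 <= self.missing_index <= N_PHASES:
            raise ValueError("missing_index must be in 1..4")

    @property
    def observed_indices(self) -> tuple[int, ...]:
        """1-based indices of the observed phases, in order."""
        return tuple(j for j in range(1, N_PHASES + 1) if j != self.missing_index)


@dataclass
class ImputationPair:
    """A complete sequence x and its decimated counterpart.

    ``filled`` is populated once a linear reconstructor has been fitted
    (see :mod:`phasegan.linear_recon`); training consumes (x, filled) pairs.
    """

    x: PhaseSequence
    incomplete: IncompleteSequence
    filled: "object | None" = None  # FilledSequence, set after linear fill


@dataclass
class PairedDataset:
    """Decimation pairs for a set of subjects (one split)."""

    pairs: list[ImputationPair] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def subject_ids(self) -> set[str]:
        return {p.x.subject_id for p in self.pairs}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def complete_sequences(self) -> list[PhaseSequence]:
        """One complete sequence per subject (deduplicated, sorted by id)."""
        by_id: dict[str, PhaseSequence] = {}
        for p in self.pairs:
            by_id.setdefault(p.x.subject_id, p.x)
        return [by_id[k] for k in sorted(by_id)]


# -- generation ----------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhaseSequence:
    """Render a spec into a 4-phase pseudo-HU sequence (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    phases = np.empty((N_PHASES, n, n))
    for p in range(N_PHASES):
        img = np.zeros((n, n))
        for comp in spec.compartments:
            rr, cc = _draw_ellipse(
                comp.center[0],
                comp.center[1],
                comp.axes[0],
                comp.axes[1],
                shape=(n, n),
                rotation=np.deg2rad(comp.angle),
            )
            img[rr, cc] = comp.enhancement[p]
        phases[p] = img
    phases += rng.normal(0.0, spec.noise_sd, size=phases.shape)
    np.clip(phases, HU_RANGE[0], HU_RANGE[1], out=phases)
    return PhaseSequence(phases, normalized=False, subject_id=f"subject-{spec.seed}")


def compartment_mask(spec: PhantomSpec, name: str) -> np.ndarray:
    """Boolean mask of the pixels whose innermost compartment is ``name``."""
    n = spec.image_size
    owner = np.full((n, n), "", dtype=object)
    for comp in spec.compartments:
        rr, cc = _draw_ellipse(
            comp.center[0],
            comp.center[1],
            comp.axes[0],
            comp.axes[1],
            shape=(n, n),
            rotation=np.deg2rad(comp.angle),
        )
        owner[rr, cc] = comp.name
    return owner == name


# -- preprocessing -------------------------------------------------------------


def normalize(seq: PhaseSequence) -> PhaseSequence:
    """Clip to [-150, 1000] pseudo-HU and map affinely onto [-1, 1]."""
    if seq.normalized:
        raise ValueError("sequence is already normalized")
    lo, hi = CLIP_RANGE
    v = np.clip(seq.phases, lo, hi)
    v = 2.0 * (v - lo) / (hi - lo) - 1.0
    return PhaseSequence(v, normalized=True, subject_id=seq.subject_id)


def denormalize(phases: np.ndarray) -> np.ndarray:
    """Inverse of the affine part of :func:`normalize` (back to pseudo-HU)."""
    lo, hi = CLIP_RANGE
    return (np.asarray(phases) + 1.0) / 2.0 * (hi - lo) + lo


def augment(
    seq: PhaseSequence,
    angles: tuple[float, ...] = (10.0, 20.0, 30.0),
    shift_fraction: float = 0.05,
) -> list[PhaseSequence]:
    """Original + rotations by +/- each angle + 4 axis shifts (at most 11).

    The same transform is applied to all four phases.  Rotations use bilinear
    interpolation with constant padding at the normalized background value.
    """
    if not seq.normalized:
        raise ValueError("augment expects a normalized sequence")
    cval = -1.0
    out = [seq]
    for a in angles:
        for sign in (1.0, -1.0):
            rot = ndimage.rotate(
                seq.phases,
                sign * a,
                axes=(1, 2),
                reshape=False,
                order=1,
                mode="constant",
                cval=cval,
            )
            out.append(
                PhaseSequence(
                    np.clip(rot, -1.0, 1.0),
                    normalized=True,
                    subject_id=f"{seq.subject_id}/rot{sign * a:+g}",
                )
            )
    d = max(1, int(round(shift_fraction * seq.phases.shape[-1])))
    for dy, dx in ((0, d), (0, -d), (d, 0), (-d, 0)):
        shifted = ndimage.shift(
            seq.phases, (0, dy, dx), order=0, mode="constant", cval=cval
        )
        out.append(
            PhaseSequence(
                shifted,
                normalized=True,
                subject_id=f"{seq.subject_id}/shift{dy:+d}{dx:+d}",
            )
        )
    return out


def decimate(seq: PhaseSequence, j: int) -> IncompleteSequence:
    """Drop phase ``j`` (1-based), keeping the other three in order."""
    if not 1 <= j <= N_PHASES:
        raise ValueError("missing index j must be in 1..4")
    keep = [p for p in range(N_PHASES) if p != j - 1]
    return IncompleteSequence(
        observed=seq.phases[keep].copy(),
        missing_index=j,
        subject_id=seq.subject_id,
    )


# -- default subject sampler ---------------------------------------------------


def _phase_curve(
    base: tuple[float, ...], amplitudes: np.ndarray, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Scale the post-contrast enhancement of a base curve and add jitter."""
    pre = base[0]
    vals = [pre + rng.normal(0.0, ENHANCEMENT_JITTER_SD)]
    for p in (2, 3, 4):
        delta = base[p - 1] - pre
        vals.append(
            pre + delta * amplitudes[p - 2] + rng.normal(0.0, ENHANCEMENT_JITTER_SD)
        )
    lo, hi = HU_RANGE
    return tuple(float(np.clip(v, lo, hi)) for v in vals)


def sample_spec(
    rng: np.random.Generator,
    image_size: int = 32,
    tumor_type: str | None = None,
) -> PhantomSpec:
    """Draw one random subject: geometry, enhancement curves, noise level."""
    n = image_size
    shared = rng.normal(0.0, AMPLITUDE_SHARED_SD)
    amps = np.array(
        [np.exp(shared + rng.normal(0.0, AMPLITUDE_SD[p])) for p in (2, 3, 4)]
    )

    def curve(name):
        return _phase_curve(BASE_CURVES[name], amps, rng)

    center = np.array([n / 2, n / 2]) + rng.uniform(-0.06 * n, 0.06 * n, size=2)
    kidney_axes = (n * rng.uniform(0.26, 0.34), n * rng.uniform(0.19, 0.25))
    angle = rng.uniform(0.0, 180.0)
    comps = [
        Compartment(
            "soft-tissue", (n / 2, n / 2), (n * 0.75, n * 0.75), 0.0,
            curve("soft-tissue"),
        ),
        Compartment("cortex", tuple(center), kidney_axes, angle, curve("cortex")),
        Compartment(
            "medulla",
            tuple(center),
            (kidney_axes[0] * 0.62, kidney_axes[1] * 0.62),
            angle,
            curve("medulla"),
        ),
        Compartment(
            "pelvis",
            tuple(center + rng.uniform(-0.03 * n, 0.03 * n, size=2)),
            (kidney_axes[0] * 0.30, kidney_axes[1] * 0.22),
            angle,
            curve("pelvis"),
        ),
    ]

    if tumor_type is None:
        tumor_type = rng.choice(TUMOR_TYPES, p=(0.5, 0.25, 0.25))
    tumor_r = n * rng.uniform(0.08, 0.16)
    theta = rng.uniform(0.0, 2 * np.pi)
    t_center = center + 0.75 * np.array(
        [kidney_axes[0] * np.sin(theta), kidney_axes[1] * np.cos(theta)]
    )
    t_center = np.clip(t_center, tumor_r + 1.0, n - tumor_r - 2.0)
    if tumor_type == "cystic-septated":
        comps.append(
            Compartment(
                "tumor", tuple(t_center), (tumor_r, tumor_r), 0.0,
                curve("cystic-fluid"),
            )
        )
        for k in range(2):
            comps.append(
                Compartment(
                    f"septum-{k}",
                    tuple(t_center),
                    (tumor_r * 0.9, max(0.6, tumor_r * 0.12)),
                    rng.uniform(0.0, 180.0),
                    curve("septum"),
                )
            )
    else:
        comps.append(
            Compartment(
                "tumor",
                tuple(t_center),
                (tumor_r, tumor_r * rng.uniform(0.7, 1.0)),
                rng.uniform(0.0, 180.0),
                curve(tumor_type),
            )
        )

    return PhantomSpec(
        image_size=n,
        compartments=tuple(comps),
        tumor_type=str(tumor_type),
        noise_sd=float(rng.uniform(*NOISE_SD_RANGE)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# -- dataset construction ------------------------------------------------------


def _pairs_for(seq: PhaseSequence) -> list[ImputationPair]:
    return [ImputationPair(x=seq, incomplete=decimate(seq, j)) for j in (1, 2, 3, 4)]


def build_dataset(
    n_subjects: int,
    image_size: int = 32,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    augment_train: bool = False,
    spec_sampler=None,
) -> tuple[PairedDataset, PairedDataset, PairedDataset]:
    """Generate subjects and build subject-disjoint train/val/test pair sets.

    Every subject contributes all four decimations, so a split with K
    complete sequences yields M = 4K pairs (times the augmentation factor
    for the training split when ``augment_train`` is set; augmented variants
    stay in the same split as their source subject).
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(split_fractions[0] * n_subjects))
    n_val = int(round(split_fractions[1] * n_subjects))
    n_test = n_subjects - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("n_subjects too small for a non-empty split")

    rng = np.random.default_rng(seed)
    sampler = spec_sampler or (lambda r: sample_spec(r, image_size=image_size))
    sequences = []
    for i in range(n_subjects):
        spec = sampler(rng)
        seq = normalize(generate_phantom(spec))
        seq.subject_id = f"S{i:04d}"
        sequences.append(seq)

    order = rng.permutation(n_subjects)
    splits = (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )
    datasets = []
    for which, idx in enumerate(splits):
        ds = PairedDataset()
        for i in idx:
            seq = sequences[i]
            variants = augment(seq) if (augment_train and which == 0) else [seq]
            for v in variants:
                ds.pairs.extend(_pairs_for(v))
        datasets.append(ds)
    return tuple(datasets)


# -- on-disk format ------------------------------------------------------------


def save_dataset(ds: PairedDataset, out_dir: str | Path) -> None:
    """One directory per subject: phases.npy [4,H,W] in [-1,1] + meta.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for seq in ds.complete_sequences():
        sub = out_dir / seq.subject_id.replace("/", "_")
        sub.mkdir(exist_ok=True)
        np.save(sub / "phases.npy", seq.phases)
        (sub / "meta.json").write_text(
            json.dumps(
                {
                    "subject_id": seq.subject_id,
                    "normalized": seq.normalized,
                    "shape": list(seq.phases.shape),
                    "phase_names": PHASE_NAMES,
                }
            )
        )


def load_dataset(in_dir: str | Path) -> PairedDataset:
    """Rebuild all four decimation pairs for every stored subject."""
    in_dir = Path(in_dir)
    ds = PairedDataset()
    for sub in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        meta = json.loads((sub / "meta.json").read_text())
        phases = np.load(sub / "phases.npy")
        seq = PhaseSequence(
            phases, normalized=meta["normalized"], subject_id=meta["subject_id"]
        )
        ds.pairs.extend(_pairs_for(seq))
    return ds


def export_png(seq: PhaseSequence, out_dir: str | Path) -> None:
    """8-bit PNG per phase (linear map of [-1, 1]), for quick visual checks."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in range(N_PHASES):
        img = ((seq.phases[p] + 1.0) / 2.0 * 255.0).clip(0, 255).astype(np.uint8)
        Image.fromarray(img).save(out_dir / f"phase{p + 1}.png")
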