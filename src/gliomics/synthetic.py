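"""Synthetic desk-scale cohorts: labeled multicontrast volumes and tabular data.

Volume cohorts emulate the structure of a preprocessed glioma study: a
nested-ellipsoid tumor carrying FeTS labels (1 = necrotic core, 4 =
enhancing shell, 2 = edema rim) embedded in four coregistered "sequences"
built from smoothed Gaussian random fields. The class signal is a *texture*
difference — the correlation length of the intratumoral field depends on the
IDH label — rather than a mean shift, so that texture features, not
first-order intensity, carry the discriminative information.

Tabular cohorts drive the selection and ensemble simulations: a configurable
number of informative features receive a class-conditional Gaussian mean
shift; the rest are standard Gaussian noise; labels follow a stated
imbalance ratio. Everything is bit-for-bit reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import LabeledMask, MRIStudy, SEQUENCES, Scheme, save_volume


@dataclass
class SyntheticCohortSpec:
    """Generation parameters for a volume cohort.

    Correlation lengths (in voxels) of the intratumoral random field are the
    class signal: IDH-mutated tumors get a coarser texture than wild type.
    Radii are in voxels and must nest (NCR core within the ET shell within
    the ED rim).
    """

    n_patients: int = 20
    mutated_fraction: float = 0.27
    volume_shape: tuple = (64, 64, 64)
    ncr_radius: tuple = (3.0, 5.0)
    et_radius: tuple = (6.0, 9.0)
    ed_radius: tuple = (10.0, 14.0)
    texture_sigma_mutated: float = 1.6
    texture_sigma_wildtype: float = 0.5
    texture_amplitude: float = 60.0
    background_mean: float = 100.0
    noise_sigma: float = 10.0
    #: per-sequence mean intensity offsets for (NCR, ET, ED) compartments
    compartment_contrast: dict = field(default_factory=lambda: {
        "T1": (-30.0, 10.0, -10.0),
        "T1c": (-20.0, 80.0, 0.0),
        "T2": (60.0, 20.0, 50.0),
        "FLAIR": (20.0, 30.0, 70.0),
    })
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mutated_fraction < 1.0:
            raise ValueError("mutated_fraction must be in (0, 1)")
        if not (self.ncr_radius[1] < self.et_radius[0]
                and self.et_radius[1] < self.ed_radius[0]):
            raise ValueError(
                "compartment radii must nest: NCR < ET < ED "
                f"(got {self.ncr_radius}, {self.et_radius}, {self.ed_radius})")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return f / f.std()


def gen_study(spec: SyntheticCohortSpec, patient_index: int, mutated: bool) -> MRIStudy:
    """One deterministic synthetic study."""
    rng = np.random.default_rng([spec.seed, patient_index])
    shape = tuple(spec.volume_shape)
    center = np.array(shape) / 2.0 + rng.uniform(-2, 2, size=3)
    r_ncr = rng.uniform(*spec.ncr_radius)
    r_et = rng.uniform(*spec.et_radius)
    r_ed = rng.uniform(*spec.ed_radius)
    # mildly anisotropic ellipsoids
    aniso = rng.uniform(0.85, 1.15, size=3)

    grids = np.indices(shape, dtype=np.float64)
    d = np.sqrt(sum(((g - c) * a) ** 2 for g, c, a in zip(grids, center, aniso)))
    seg = np.zeros(shape, dtype=np.int16)
    seg[d <= r_ed] = 2
    seg[d <= r_et] = 4
    seg[d <= r_ncr] = 1
    tumor = seg > 0

    sigma = spec.texture_sigma_mutated if mutated else spec.texture_sigma_wildtype
    sequences = {}
    for tag in SEQUENCES:
        background = spec.background_mean + 15.0 * _smooth_field(rng, shape, 4.0)
        texture = spec.texture_amplitude * _smooth_field(rng, shape, sigma)
        vol = background + rng.standard_normal(shape) * spec.noise_sigma
        vol[tumor] += texture[tumor]
        for label, offset in zip((1, 4, 2), spec.compartment_contrast[tag]):
            vol[seg == label] += offset
        sequences[tag] = vol
    return MRIStudy(
        patient_id=f"SYN{patient_index:04d}",
        sequences=sequences,
        spacing_mm=(1.0, 1.0, 1.0),
        segmentation=LabeledMask(voxels=seg, scheme=Scheme.FETS),
    )


def gen_volume_cohort(spec: SyntheticCohortSpec, out_dir: str | Path | None = None):
    """Generate (study, label) pairs; optionally write NIfTI files + manifest.

    Labels are assigned deterministically: ``round(n * mutated_fraction)``
    patients are mutated, in a seed-shuffled order.
    """
    n = spec.n_patients
    n_mut = int(round(n * spec.mutated_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_mut] = 1
    np.random.default_rng([spec.seed, 999_983]).shuffle(labels)

    studies = [gen_study(spec, i, bool(labels[i])) for i in range(n)]

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for study, label in zip(studies, labels):
            pid = study.patient_id
            paths = {}
            for tag in SEQUENCES:
                p = out_dir / f"{pid}_{tag}.nii.gz"
                save_volume(study.sequences[tag].astype(np.float32),
                            study.spacing_mm, p)
                paths[tag.lower()] = str(p)
            seg_path = out_dir / f"{pid}_seg.nii.gz"
            save_volume(study.segmentation.voxels, study.spacing_mm, seg_path)
            rows.append({
                "patient_id": pid, "t1": paths["t1"], "t1c": paths["t1c"],
                "t2": paths["t2"], "flair": paths["flair"],
                "seg": str(seg_path), "scheme": "FETS", "idh": int(label),
            })
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return list(zip(studies, labels.tolist())), manifest


def gen_tabular_cohort(n: int, p: int, n_informative: int, effect_size: float,
                       imbalance_ratio: float, seed: int = 0):
    """Tabular cohort with mean-shifted informative features.

    The first ``n_informative`` columns get a class-conditional mean shift of
    ``effect_size`` (in units of the unit feature SD) for the minority
    (mutated) class. Class counts follow ``imbalance_ratio`` (majority to
    minority) to within rounding.
    """
    if n_informative > p:
        raise ValueError("n_informative must not exceed p")
    if imbalance_ratio < 1:
        raise ValueError("imbalance_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    n_minority = int(round(n / (1.0 + imbalance_ratio)))
    n_minority = max(n_minority, 1)
    y = np.zeros(n, dtype=int)
    y[:n_minority] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n, p))
    X[:, :n_informative] += effect_size * y[:, None]
    return X, y
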