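"""Synthetic two-modality MRI phantom cohorts with planted class texture.

Each phantom carries an ellipsoidal tumor mask shared by both modalities
(CET1-w, T2-w).  Within-mask intensities follow a smoothed Gaussian random
field: white noise convolved with an isotropic Gaussian kernel whose width
(spatial correlation length) and mean level depend on the progression class,
so that both first-order and texture features can carry class signal.
Outside the mask lies independent background noise at a distinct mean; the
extraction stage never reads it.

Follow-up times are constructed to make the 3-year dichotomization
unambiguous: progressors get an event time Uniform(3, 36) months and
non-progressors a follow-up time Uniform(37, 89) months, matching the
observed 3-89 month follow-up range of the cohort the generator emulates.

A second, feature-level generator (:func:`simulate_feature_cohort`) skips
the imaging entirely and plants informative columns directly in a
970-feature matrix; it drives the selection/recovery calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import TumorMask, VolumeImage, write_mask, write_volume
from .names import MODALITIES, canonical_names


@dataclass
class ClassEffect:
    """Per-class texture parameters planted in the phantoms.

    mean_shift: added to the in-mask mean of class-1 (progression) phantoms,
    in intensity units.  corr_length_mm: Gaussian-kernel correlation length
    of the within-mask field, (class 0, class 1), in mm.  noise_sd: standard
    deviation of the within-mask field in intensity units (both classes).
    """

    mean_shift: float = 10.0
    corr_length_mm: tuple[float, float] = (2.0, 3.5)
    noise_sd: float = 10.0


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a phantom cohort.

    Defaults emulate the cohort structure the package targets: 80 training
    + 33 validation patients, anisotropic voxels (4 mm slices), tumors of
    14-18 mm semi-axes.  Intensity scales are arbitrary (no public tumor
    intensity distributions exist to match) and documented as such.
    """

    n_train: int = 80
    n_val: int = 33
    prevalence: float = 0.3
    grid_shape: tuple[int, int, int] = (44, 44, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    tumor_radius_range: tuple[float, float] = (14.0, 18.0)  # mm, per-axis semi-axes
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    intensity_mean: float = 100.0  # in-mask class-0 mean
    background_mean: float = 40.0
    background_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_train <= 0 or self.n_val <= 0:
            raise ValueError("n_train and n_val must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 4 voxels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_range must be 0 < lo <= hi")
        half_extent = [
            n * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing)
        ]
        if any(hi >= h for h in half_extent):
            raise ValueError(
                f"tumor radius {hi} mm exceeds half the grid extent "
                f"{tuple(round(h, 1) for h in half_extent)} mm"
            )


@dataclass
class SyntheticPatient:
    id: str
    volumes: dict[str, VolumeImage]  # modality -> volume
    mask: TumorMask
    true_label: int
    followup_months: float


def generate_phantom(
    config: SyntheticCohortConfig, label: int, rng: np.random.Generator, patient_id: str = "P000"
) -> SyntheticPatient:
    """One two-modality phantom with class-dependent within-mask texture."""
    config.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=float)

    # ellipsoidal mask: per-axis semi-axes in mm, center jittered by <= 1 voxel
    lo, hi = config.tumor_radius_range
    radii = rng.uniform(lo, hi, size=3)
    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    dist2 = sum(
        ((g - c) * s / r) ** 2 for g, c, s, r in zip(grids, center, spacing, radii)
    )
    mask_arr = dist2 <= 1.0
    mask = TumorMask(mask_arr, tuple(spacing))

    eff = config.class_effect
    corr = eff.corr_length_mm[label]
    sigma_vox = corr / spacing  # kernel width in voxel units per axis
    in_mean = config.intensity_mean + (eff.mean_shift if label == 1 else 0.0)

    volumes: dict[str, VolumeImage] = {}
    for mod in MODALITIES:
        white = rng.standard_normal(shape)
        smooth = gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        sd = smooth.std()
        field_ = smooth / sd * eff.noise_sd if sd > 0 else smooth
        background = config.background_mean + config.background_sd * rng.standard_normal(shape)
        vol = np.where(mask_arr, in_mean + field_, background)
        volumes[mod] = VolumeImage(vol, tuple(spacing), mod)

    followup = float(rng.uniform(3.0, 36.0)) if label == 1 else float(rng.uniform(37.0, 89.0))
    return SyntheticPatient(patient_id, volumes, mask, label, followup)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """A full phantom cohort plus its clinical table.

    Labels are Bernoulli(prevalence); the first ``n_train`` patients form the
    training cohort.  Identical (config, seed) reproduces the cohort
    bit-for-bit: every patient draws from its own spawned RNG stream.
    """
    config.validate()
    n = config.n_train + config.n_val
    root = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = (label_rng.random(n) < config.prevalence).astype(int)
    streams = root.spawn(1)[0].spawn(n)  # reserve one child per patient
    patients = []
    rows = []
    for i in range(n):
        pid = f"SYN{i:03d}"
        rng = np.random.default_rng(streams[i])
        p = generate_phantom(config, int(labels[i]), rng, pid)
        cohort = "training" if i < config.n_train else "validation"
        patients.append(p)
        rows.append(
            {
                "id": pid,
                "label": p.true_label,
                "followup_months": p.followup_months,
                "cohort": cohort,
            }
        )
    clinical = pd.DataFrame(rows)
    return patients, clinical


def write_cohort(patients, clinical: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write per-patient NIfTI files plus the cohort CSV; returns the table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = clinical.copy()
    paths: dict[str, list[str]] = {"cet1_path": [], "t2_path": [], "mask_path": []}
    for p in patients:
        cet1 = outdir / f"{p.id}_CET1-w.nii.gz"
        t2 = outdir / f"{p.id}_T2-w.nii.gz"
        msk = outdir / f"{p.id}_mask.nii.gz"
        write_volume(p.volumes["CET1-w"], cet1)
        write_volume(p.volumes["T2-w"], t2)
        write_mask(p.mask, msk)
        paths["cet1_path"].append(cet1.name)
        paths["t2_path"].append(t2.name)
        paths["mask_path"].append(msk.name)
    for col, vals in paths.items():
        table[col] = vals
    table = table[["id", "cet1_path", "t2_path", "mask_path", "label", "followup_months", "cohort"]]
    table.to_csv(outdir / "cohort.csv", index=False)
    return table


def simulate_feature_cohort(
    n_train: int = 80,
    n_val: int = 33,
    n_informative_per_modality: int = 4,
    effect: float = 1.0,
    prevalence: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray, list[str]]:
    """Feature-level cohort: a 970-column standard-normal matrix with planted signal.

    ``n_informative_per_modality`` columns per modality (canonical names,
    chosen at random) get their class-1 mean shifted by ``effect`` standard
    deviations.  Labels are Bernoulli(prevalence), redrawn until both classes
    have at least 2 members in each cohort so downstream fits are defined.

    Returns (X_train, y_train, X_val, y_val, informative_names).
    """
    rng = np.random.default_rng(seed)
    cols = canonical_names()
    informative: list[str] = []
    for mod in MODALITIES:
        mod_cols = [c for c in cols if c.startswith(mod + "_")]
        picked = rng.choice(len(mod_cols), size=n_informative_per_modality, replace=False)
        informative.extend(mod_cols[i] for i in sorted(picked))

    def draw(n: int) -> tuple[pd.DataFrame, np.ndarray]:
        for _ in range(1000):
            y = (rng.random(n) < prevalence).astype(int)
            if 2 <= y.sum() <= n - 2:
                break
        else:
            raise RuntimeError("could not draw a two-class label vector")
        x = pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols)
        x.loc[y == 1, informative] += effect
        return x, y

    x_tr, y_tr = draw(n_train)
    x_va, y_va = draw(n_val)
    return x_tr, y_tr, x_va, y_va, informative
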