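"""Synthetic lifespan cohorts with planted age effects on local coherence.

Emulates the structure of a lifespan resting-state cohort (ages 18-88,
sex-balanced, ~260-volume EPI runs at TR 1.97 s) at desk scale, so every
downstream stage — preprocessing, the local statistics and the group GLM —
can be exercised against known ground truth.

The planted effect is local signal *coherence*: voxels inside a designated
region share a latent time series s_R(t) mixed with voxel noise,

    x_v(t) = baseline + noise_sd * ( w * s_R(t) + sqrt(1 - w^2) * eps_v(t) ),

with s_R and eps_v independent unit-variance white noise, so the expected
pairwise correlation between two region voxels is exactly w^2. Choosing
w = sqrt(c) plants coherence c, and c is made an explicit function of age:

    c(age) = base_coherence + linear_slope*(age - a0) + quadratic_coeff*(age - a0)^2

where a0 is the cohort mean age (the midpoint of a uniform age range).
Voxels outside every region are noise with a mild spatial point-spread
(neighboring voxels weakly correlated, as in acquired EPI; temporally white)
plus a shared global signal. Motion traces are bounded random walks;
phenotype scores decline
(fluid intelligence) or rise (reaction times) linearly with age plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import MotionTrace, VolumeSeries

__all__ = [
    "EffectRegion",
    "CohortSpec",
    "block_region",
    "ellipsoid_mask",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "default_spec",
]

BASELINE = 1000.0  # raw-signal offset, keeps tSNR = baseline/noise_sd well above the gate
COHERENCE_BOUNDS = (0.01, 0.99)


class InvalidSpecError(ValueError):
    """Raised when a planted effect leaves the valid coherence range."""


@dataclass(frozen=True)
class EffectRegion:
    """A voxel set carrying an age-dependent planted coherence.

    ``linear_slope`` is coherence change per year; ``quadratic_coeff`` per
    year^2, both about the cohort mean age.
    """

    voxels: tuple[tuple[int, int, int], ...]
    base_coherence: float
    linear_slope: float = 0.0
    quadratic_coeff: float = 0.0
    name: str = "region"

    def coherence_at(self, age: float, mean_age: float) -> float:
        d = age - mean_age
        return self.base_coherence + self.linear_slope * d + self.quadratic_coeff * d * d

    def index(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
        arr = np.array(self.voxels, dtype=np.intp)
        return (arr[:, 0], arr[:, 1], arr[:, 2])


def block_region(corner: tuple[int, int, int], size: tuple[int, int, int] | int,
                 **kwargs) -> EffectRegion:
    """A rectangular-block effect region, the usual test-bed shape."""
    if isinstance(size, int):
        size = (size, size, size)
    voxels = tuple(
        (i, j, k)
        for i in range(corner[0], corner[0] + size[0])
        for j in range(corner[1], corner[1] + size[1])
        for k in range(corner[2], corner[2] + size[2])
    )
    return EffectRegion(voxels=voxels, **kwargs)


def ellipsoid_mask(shape: tuple[int, int, int], radius_frac: float = 0.45) -> np.ndarray:
    """Inscribed-ellipsoid brain mask, a crude head-shaped support."""
    center = (np.array(shape) - 1) / 2.0
    radii = np.array(shape) * radius_frac
    ii, jj, kk = np.indices(shape)
    d2 = (
        ((ii - center[0]) / radii[0]) ** 2
        + ((jj - center[1]) / radii[1]) ** 2
        + ((kk - center[2]) / radii[2]) ** 2
    )
    return d2 <= 1.0


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the RNG seed makes it a
    reproducible artifact (identical spec => identical arrays)."""

    n_subjects: int = 100
    age_range: tuple[float, float] = (18.0, 88.0)
    sex_ratio: float = 0.5  # fraction male
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_timepoints: int = 200
    tr: float = 1.97
    effect_regions: list[EffectRegion] = field(default_factory=list)
    noise_sd: float = 10.0
    global_signal_sd: float = 3.0
    motion_sd: float = 0.02  # per-step translation sd (mm); rotations use motion_sd/50 rad
    noise_smooth_sigma: float = 0.35  # voxels; spatial PSF of background noise
    temporal_ar1: float = 0.3  # lag-1 autocorrelation of all signal sources
    seed: int = 0
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2")
        if self.n_timepoints < 20:
            raise InvalidSpecError("n_timepoints must be >= 20")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidSpecError("age_range low must be < high")
        seen: set[tuple[int, int, int]] = set()
        mask = self.brain_mask()
        for region in self.effect_regions:
            vox = set(region.voxels)
            if vox & seen:
                raise InvalidSpecError("effect regions must be disjoint")
            seen |= vox
            for v in region.voxels:
                if not mask[v]:
                    raise InvalidSpecError(f"region voxel {v} outside the brain mask")
            self._check_coherence(region)

    def _check_coherence(self, region: EffectRegion) -> None:
        lo, hi = self.age_range
        a0 = self.mean_age
        candidates = [lo, hi]
        if region.quadratic_coeff != 0:
            vertex = a0 - region.linear_slope / (2 * region.quadratic_coeff)
            if lo <= vertex <= hi:
                candidates.append(vertex)
        for age in candidates:
            c = region.coherence_at(age, a0)
            if not (COHERENCE_BOUNDS[0] <= c <= COHERENCE_BOUNDS[1]):
                raise InvalidSpecError(
                    f"region {region.name!r}: coherence {c:.3f} at age {age:.1f} "
                    f"outside {COHERENCE_BOUNDS}"
                )

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape)

    def tissue_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Stand-in white-matter and CSF masks: two small blocks inside the
        brain mask, away from the default effect regions."""
        nx, ny, nz = self.grid_shape
        wm = np.zeros(self.grid_shape, dtype=bool)
        csf = np.zeros(self.grid_shape, dtype=bool)
        cx, cz = nx // 2 - 1, nz // 2 - 1
        wm[cx : cx + 3, ny // 5 : ny // 5 + 3, cz : cz + 3] = True
        csf[cx : cx + 3, 4 * ny // 5 - 2 : 4 * ny // 5 + 1, cz : cz + 3] = True
        brain = self.brain_mask()
        return wm & brain, csf & brain

    def subject_rng(self, subject_seed: int) -> np.random.Generator:
        # one stream per subject, split by counter: reproducible regardless
        # of how many subjects are generated before this one; counter 0 is
        # reserved for cohort-level draws, subjects use 1..n
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(subject_seed + 1,))
        )


def default_spec(**overrides) -> CohortSpec:
    """The reference study conditions: a 20^3 grid, 200 frames at TR 1.97 s,
    100 subjects aged 18-88, one region whose coherence declines with age and
    one whose coherence rises (0.004/yr either way around base 0.5)."""
    regions = overrides.pop(
        "effect_regions",
        [
            block_region((4, 8, 8), 4, base_coherence=0.5, linear_slope=-0.004,
                         name="declining"),
            block_region((12, 8, 8), 4, base_coherence=0.5, linear_slope=+0.004,
                         name="rising"),
        ],
    )
    return CohortSpec(effect_regions=regions, **overrides)


def _color_ar1(white: np.ndarray, phi: float) -> np.ndarray:
    """AR(1) coloring along the last axis, unit marginal variance.

    Applied identically to every stochastic source (latents, voxel noise,
    global signal), so expected pairwise correlations are unchanged; only
    the effective temporal degrees of freedom shrink, as in acquired BOLD.
    """
    if phi == 0:
        return white
    from scipy.signal import lfilter

    return lfilter([np.sqrt(1.0 - phi * phi)], [1.0, -phi], white, axis=-1)


def _bounded_walk(rng: np.random.Generator, n: int, step_sd: float,
                  bound: float) -> np.ndarray:
    """Random walk reflected at +/- bound; starts at zero."""
    if step_sd == 0:
        return np.zeros(n)
    steps = rng.normal(0.0, step_sd, size=n)
    steps[0] = 0.0
    walk = np.cumsum(steps)
    if bound > 0:
        # reflect into [-bound, bound]
        walk = np.abs((walk + bound) % (4 * bound) - 2 * bound) - bound
    return walk


def generate_subject(
    spec: CohortSpec, age: float, subject_seed: int
) -> tuple[VolumeSeries, MotionTrace]:
    """One subject's 4D volume and motion trace at the given age.

    Region voxels mix the region latent with voxel noise at the age-specific
    coherence; other in-mask voxels get spatially point-spread noise plus the
    shared global signal; out-of-mask voxels are zero. The motion trace is a
    bounded random walk, zero when ``motion_sd`` is 0.
    """
    lo, hi = spec.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside spec range {spec.age_range}")
    rng = spec.subject_rng(subject_seed)
    shape = spec.grid_shape
    t = spec.n_timepoints
    mask = spec.brain_mask()

    # background: unit-variance noise with a small spatial point-spread
    # (neighboring voxels mildly correlated, as in acquired EPI), plus the
    # shared global signal, on top of a constant baseline
    noise = _color_ar1(
        rng.standard_normal((*shape, t), dtype=np.float32), spec.temporal_ar1
    )
    if spec.noise_smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        sig = spec.noise_smooth_sigma
        noise = gaussian_filter(noise, sigma=(sig, sig, sig, 0.0), mode="constant")
        # restore unit variance: divide by the kernel's l2 norm
        delta = np.zeros((9, 9, 9))
        delta[4, 4, 4] = 1.0
        kernel = gaussian_filter(delta, sigma=sig, mode="constant")
        noise /= np.float32(np.sqrt((kernel**2).sum()))
    global_signal = _color_ar1(
        rng.standard_normal(t, dtype=np.float32), spec.temporal_ar1
    )
    data = np.where(
        mask[..., None],
        np.float32(BASELINE)
        + np.float32(spec.global_signal_sd) * global_signal
        + np.float32(spec.noise_sd) * noise,
        np.float32(0.0),
    )

    a0 = spec.mean_age
    for region in spec.effect_regions:
        c = region.coherence_at(age, a0)
        if not (COHERENCE_BOUNDS[0] <= c <= COHERENCE_BOUNDS[1]):
            raise InvalidSpecError(
                f"region {region.name!r}: coherence {c:.3f} at age {age:.1f}"
            )
        w = np.float32(np.sqrt(c))
        latent = _color_ar1(rng.standard_normal(t, dtype=np.float32), spec.temporal_ar1)
        idx = region.index(shape)
        eps = _color_ar1(
            rng.standard_normal((len(region.voxels), t), dtype=np.float32),
            spec.temporal_ar1,
        )
        if spec.noise_sd == 0:
            # no voxel noise: the latent alone drives every region voxel,
            # so all within-region pairs correlate exactly 1
            data[idx] = np.float32(BASELINE) + w * latent[None, :]
        else:
            data[idx] = np.float32(BASELINE) + np.float32(spec.noise_sd) * (
                w * latent[None, :] + np.sqrt(np.float32(1.0) - w * w) * eps
            )

    trans_bound, rot_bound = 1.0, 0.02  # mm, rad
    params = np.zeros((t, 6))
    for j in range(3):
        params[:, j] = _bounded_walk(rng, t, spec.motion_sd, trans_bound)
    for j in range(3, 6):
        params[:, j] = _bounded_walk(rng, t, spec.motion_sd / 50.0, rot_bound)

    vol = VolumeSeries(data=data, affine=spec.affine, tr=spec.tr, mask=mask)
    return vol, MotionTrace(params)


def _phenotypes(rng: np.random.Generator, ages: np.ndarray) -> dict[str, np.ndarray]:
    """Age-linked behavior scores and intracranial volume.

    Fluid-intelligence (Cattell-like, scale ~12-44) declines linearly with
    age; mean and variability of choice reaction time rise. ICV is lognormal
    around 1.45e6 mm^3 and age-independent.
    """
    n = len(ages)
    icv = rng.lognormal(mean=np.log(1.45e6), sigma=0.08, size=n)
    cattell = 42.4 - 0.18 * ages + rng.normal(0, 4.2, size=n)
    rt_m = 0.40 + 0.005 * (ages - 18.0) + rng.normal(0, 0.08, size=n)
    rt_sd = 0.06 + 0.0017 * (ages - 18.0) + rng.normal(0, 0.03, size=n)
    return {
        "icv": icv,
        "cattell": cattell,
        "rt_m": np.maximum(rt_m, 0.05),
        "rt_sd": np.maximum(rt_sd, 0.01),
    }


def cohort_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Cohort-level draws only: ages (uniform over the range), sex
    (Bernoulli at sex_ratio), ICV and behavior scores. Subject i's imaging
    data is then ``generate_subject(spec, table.age[i], i)``."""
    cohort_rng = spec.subject_rng(-1)  # counter 0: cohort-level draws
    n = spec.n_subjects
    ages = cohort_rng.uniform(*spec.age_range, size=n)
    sex = np.where(cohort_rng.random(n) < spec.sex_ratio, "M", "F")
    pheno = _phenotypes(cohort_rng, ages)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            **pheno,
        }
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[VolumeSeries, MotionTrace]], pd.DataFrame]:
    """Generate every subject plus the cohort phenotype table.

    Everything is reproducible from ``spec.seed`` alone; for large cohorts
    prefer ``cohort_phenotypes`` plus per-subject ``generate_subject`` to
    avoid holding every 4D volume in memory.
    """
    table = cohort_phenotypes(spec)
    subjects = [
        generate_subject(spec, float(age), i) for i, age in enumerate(table["age"])
    ]
    return subjects, table


def write_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Materialize a cohort on disk: per-subject NIfTI + rp text files,
    brain/WM/CSF masks and the phenotype TSV. Returns the phenotype table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, table = generate_cohort(spec)
    aff = spec.affine
    nib.save(nib.Nifti1Image(spec.brain_mask().astype(np.uint8), aff), out / "mask_brain.nii.gz")
    wm, csf = spec.tissue_masks()
    nib.save(nib.Nifti1Image(wm.astype(np.uint8), aff), out / "mask_wm.nii.gz")
    nib.save(nib.Nifti1Image(csf.astype(np.uint8), aff), out / "mask_csf.nii.gz")
    for (vol, motion), sid in zip(subjects, table["subject_id"]):
        nib.save(vol.to_nifti(), out / f"{sid}_bold.nii.gz")
        motion.to_file(out / f"rp_{sid}.txt")
    table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    return table
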