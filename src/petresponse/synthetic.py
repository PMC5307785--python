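"""Synthetic paired pre/post-treatment lesion cohorts.

Each patient belongs to one of four response classes whose effect on the
post-treatment image is encoded as multiplicative post/pre ratios of lesion
peak intensity and radius:

* ``negative``          — lesion grows and brightens (ratios > 1);
* ``neutral``           — no change beyond noise (ratios = 1);
* ``positive_partial``  — lesion shrinks and dims but stays detectable;
* ``positive_complete`` — lesion gone; the post image is background noise.

The lesion is an analytic radially decreasing profile
``peak * 0.4 ** ((r / radius) ** 2)`` — calibrated so the profile crosses
40% of peak exactly at ``r = radius`` — multiplied inside its support by a
smooth Gaussian-random-field texture, plus additive background noise.  The
ground-truth mask is the set of pixels whose noiseless, pre-modulation
profile is at least 40% of peak, i.e. the disc ``r <= radius``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .segmentation import LesionMask, ScanImage

RESPONSE_CLASSES = ("negative", "neutral", "positive_partial", "positive_complete")

#: Fraction of peak at which the analytic lesion profile defines the mask.
PROFILE_MASK_FRACTION = 0.4
#: Profile support cutoff, in lesion radii (profile is 0 beyond this).
PROFILE_CUTOFF_RADII = 3.0
#: Background noise is truncated at this many SDs so a "complete" response
#: post image never shows a supra-threshold pixel.
NOISE_TRUNCATION_SD = 2.9

DEFAULT_CLASS_COUNTS = {
    "negative": 2,
    "neutral": 6,
    "positive_partial": 27,
    "positive_complete": 28,
}

#: Per-class (post/pre intensity ratio, post/pre radius ratio).
DEFAULT_EFFECTS = {
    "negative": (1.35, 1.60),
    "neutral": (1.0, 1.0),
    "positive_partial": (0.70, 0.50),
    "positive_complete": (0.0, 0.0),
}


@dataclass
class ClinicalRecord:
    """The 8 per-patient clinical variables."""

    age: float
    tumor_stage: int
    weight_pre: float
    weight_post: float
    suvmax_lesion_pre: float
    suvmax_lesion_post: float
    suvmax_reference_pre: float
    suvmax_reference_post: float

    FIELDS = (
        "age", "tumor_stage", "weight_pre", "weight_post",
        "suvmax_lesion_pre", "suvmax_lesion_post",
        "suvmax_reference_pre", "suvmax_reference_post",
    )

    def __post_init__(self) -> None:
        self.tumor_stage = int(self.tumor_stage)
        if not 1 <= self.tumor_stage <= 4:
            raise ConfigurationError(f"tumor_stage must be in 1..4, got {self.tumor_stage}")
        for name in self.FIELDS:
            value = float(getattr(self, name))
            if not (np.isfinite(value) and value > 0):
                raise ConfigurationError(f"clinical variable {name!r} must be positive, got {value}")

    def as_vector(self) -> np.ndarray:
        return np.array([float(getattr(self, n)) for n in self.FIELDS])


@dataclass
class CohortConfig:
    """Parameters of cohort generation; identical config + seed gives a
    byte-identical cohort."""

    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    image_size: int = 64
    # The defaults are deliberately a high-separation regime (narrow
    # radius spread, mild texture/noise): the class-conditional size and
    # intensity effects then dominate the principal components, the
    # synthetic analogue of the clean class structure the pipeline targets.
    lesion_radius_range: tuple[float, float] = (9.5, 9.5)
    lesion_peak_range: tuple[float, float] = (0.55, 0.65)
    texture_smoothness: float = 4.0
    texture_amplitude: float = 0.02
    background_noise_sd: float = 0.005
    effects: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    suv_scale: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        for cls in self.class_counts:
            if cls not in RESPONSE_CLASSES:
                raise ConfigurationError(f"class_counts: unknown response class {cls!r}")
        for cls, count in self.class_counts.items():
            if int(count) < 0:
                raise ConfigurationError(f"class_counts[{cls!r}] must be non-negative, got {count}")
        if sum(int(c) for c in self.class_counts.values()) <= 0:
            raise ConfigurationError("class_counts: total cohort size must be positive")
        if self.image_size < 8:
            raise ConfigurationError(f"image_size must be >= 8, got {self.image_size}")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"lesion_radius_range must be a non-empty positive interval, got {self.lesion_radius_range}")
        if hi >= self.image_size / 2:
            raise ConfigurationError(
                f"lesion_radius_range: maximum radius {hi} does not fit in image_size {self.image_size}"
            )
        plo, phi = self.lesion_peak_range
        if not (0 < plo <= phi <= 1.0):
            raise ConfigurationError(f"lesion_peak_range must lie within (0, 1], got {self.lesion_peak_range}")
        if self.texture_smoothness <= 0:
            raise ConfigurationError("texture_smoothness must be positive")
        if self.texture_amplitude < 0 or self.background_noise_sd < 0:
            raise ConfigurationError("texture_amplitude and background_noise_sd must be non-negative")
        for cls in RESPONSE_CLASSES:
            if cls not in self.effects:
                raise ConfigurationError(f"effects: missing response class {cls!r}")


@dataclass
class SyntheticPatient:
    id: str
    label: str
    pre_image: ScanImage
    post_image: ScanImage
    clinical: ClinicalRecord
    ground_truth_mask_pre: LesionMask
    ground_truth_mask_post: LesionMask


def _texture_field(shape: tuple[int, int], smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD smooth random field (correlation length ~smoothness)."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else np.zeros(shape)


def generate_lesion_image(
    size: int,
    center: tuple[float, float],
    radius: float,
    peak: float,
    smoothness: float = 4.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    texture_amplitude: float = 0.0,
) -> tuple[ScanImage, LesionMask]:
    """Generate one lesion image and its analytic ground-truth mask.

    Returns intensities in ``[0, 1]``; the mask marks pixels whose noiseless
    radial profile is at least 40% of peak (a disc of the given radius).
    """
    if not (0.0 < peak <= 1.0):
        raise ConfigurationError(f"peak must lie in (0, 1], got {peak}")
    if radius <= 0:
        raise ConfigurationError(f"radius must be positive, got {radius}")
    cr, cc = center
    if not (radius <= cr <= size - 1 - radius and radius <= cc <= size - 1 - radius):
        raise ConfigurationError(
            f"lesion (center={center}, radius={radius}) does not fit in a {size}x{size} image"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dist = np.hypot(rows - cr, cols - cc)
    profile = peak * PROFILE_MASK_FRACTION ** ((dist / radius) ** 2)
    profile[dist > PROFILE_CUTOFF_RADII * radius] = 0.0
    # The mask is relative to the attained grid maximum (the profile at the
    # pixel nearest the continuous center): exactly the reference a
    # seeded-at-the-maximum relative-threshold segmentation uses.
    mask = profile >= PROFILE_MASK_FRACTION * profile.max()

    image = profile.copy()
    if texture_amplitude > 0:
        texture = _texture_field((size, size), smoothness, rng)
        support = profile > 0
        image[support] = profile[support] * (1.0 + texture_amplitude * texture[support])
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=(size, size))
    return ScanImage(np.clip(image, 0.0, 1.0)), LesionMask(mask)


def _background_image(size: int, noise_sd: float, rng: np.random.Generator) -> ScanImage:
    """Lesion-free image: truncated background noise only."""
    if noise_sd == 0:
        return ScanImage(np.zeros((size, size)))
    noise = rng.normal(0.0, noise_sd, size=(size, size))
    return ScanImage(np.clip(noise, 0.0, NOISE_TRUNCATION_SD * noise_sd))


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full cohort, class by class, deterministically.

    Patients are emitted in fixed response-class order; all randomness flows
    from ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    size = config.image_size
    patients: list[SyntheticPatient] = []
    index = 0
    for label in RESPONSE_CLASSES:
        for _ in range(int(config.class_counts.get(label, 0))):
            intensity_ratio, radius_ratio = config.effects[label]
            radius = rng.uniform(*config.lesion_radius_range)
            peak = rng.uniform(*config.lesion_peak_range)
            max_radius = radius * max(1.0, radius_ratio)
            margin = max_radius + 1.0
            cr = rng.uniform(margin, size - 1 - margin)
            cc = rng.uniform(margin, size - 1 - margin)

            pre_image, pre_mask = generate_lesion_image(
                size, (cr, cc), radius, peak,
                smoothness=config.texture_smoothness,
                noise_sd=config.background_noise_sd,
                rng=rng,
                texture_amplitude=config.texture_amplitude,
            )
            if label == "positive_complete":
                post_image = _background_image(size, config.background_noise_sd, rng)
                post_mask = LesionMask(np.zeros((size, size), dtype=bool))
                post_peak = 0.0
            else:
                post_peak = min(0.97, peak * intensity_ratio)
                post_radius = radius * radius_ratio
                post_image, post_mask = generate_lesion_image(
                    size, (cr, cc), post_radius, post_peak,
                    smoothness=config.texture_smoothness,
                    noise_sd=config.background_noise_sd,
                    rng=rng,
                    texture_amplitude=config.texture_amplitude,
                )

            weight_pre = rng.uniform(40.0, 120.0)
            clinical = ClinicalRecord(
                age=rng.uniform(18.0, 85.0),
                tumor_stage=int(rng.integers(1, 5)),
                weight_pre=weight_pre,
                weight_post=weight_pre * rng.normal(1.0, 0.03),
                suvmax_lesion_pre=peak * config.suv_scale,
                suvmax_lesion_post=max(0.05, post_peak * config.suv_scale),
                suvmax_reference_pre=rng.uniform(1.0, 3.0),
                suvmax_reference_post=rng.uniform(1.0, 3.0),
            )
            patients.append(
                SyntheticPatient(
                    id=f"P{index:03d}",
                    label=label,
                    pre_image=pre_image,
                    post_image=post_image,
                    clinical=clinical,
                    ground_truth_mask_pre=pre_mask,
                    ground_truth_mask_post=post_mask,
                )
            )
            index += 1
    return patients
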