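"""Synthetic 3D PET-like phantom cohorts.

The downstream analysis (segmentation agreement, feature reproducibility,
classification) needs volumes with a hot, mildly heterogeneous lesion on a
noisy background, two scanner voxel geometries, and a binary grade label with
a tunable class effect.  This module generates such cohorts deterministically
from a seed; it emulates acquisition geometry and lesion statistics, not PET
physics (no attenuation, PSF or reconstruction modelling).

Arrays use axis order (x, y, z); ``spacing`` is mm per axis in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "ScanCase",
    "MaskPerturbationError",
    "generate_phantom",
    "perturb_mask",
    "generate_cohort",
    "GEOMETRY_GE",
    "GEOMETRY_SIEMENS",
]

#: Voxel geometries of the two emulated scanner groups (mm).
GEOMETRY_GE = (2.73, 2.73, 3.27)
GEOMETRY_SIEMENS = (1.45, 1.45, 3.0)

#: Grid shapes paired with the geometries, sized so a <=15 mm-radius lesion
#: fits with margin while keeping volumes small.
_GRID_FOR_GEOMETRY = {
    GEOMETRY_GE: (36, 36, 28),
    GEOMETRY_SIEMENS: (56, 56, 30),
}


class MaskPerturbationError(RuntimeError):
    """Raised when a boundary perturbation empties a mask even after damping."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and intensity description of a single-lesion phantom.

    All lengths are mm; intensities are arbitrary uptake units.
    ``heterogeneity_amplitude`` scales a spatially correlated intra-lesion
    texture field with unit standard deviation, so its value is the texture
    standard deviation in uptake units.
    """

    grid_shape: tuple[int, int, int] = (36, 36, 28)
    spacing: tuple[float, float, float] = GEOMETRY_GE
    lesion_center: tuple[float, float, float] | None = None
    lesion_radii: tuple[float, float, float] = (11.0, 11.0, 11.0)
    core_intensity: float = 10.0
    rim_intensity: float = 6.0
    background_intensity: float = 1.0
    noise_sd: float = 0.5
    noise_fwhm_mm: float = 5.0  # reconstruction-like noise correlation length
    heterogeneity_amplitude: float = 1.0
    core_fraction: float = 0.6  # normalized radius below which uptake is core-level

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(r <= 0 for r in self.lesion_radii):
            raise ValueError("lesion_radii must be strictly positive")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.heterogeneity_amplitude < 0:
            raise ValueError("heterogeneity_amplitude must be >= 0")
        center = self.center_mm
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        for c, r, e in zip(center, self.lesion_radii, extent):
            if c - r < 0 or c + r > e:
                raise ValueError(
                    f"lesion (center {center}, radii {self.lesion_radii} mm) "
                    f"does not fit inside the grid extent {extent} mm"
                )

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.lesion_center is not None:
            return self.lesion_center
        return tuple(n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and class-effect settings.

    ``effect`` is the mean shift, in units of the within-class standard
    deviation, applied to the high-grade lesion texture parameter
    (heterogeneity amplitude).  ``geometry_mix`` is the fraction of subjects
    on the coarser (GE-like) voxel grid; the default mirrors the 29/78 split
    of the emulated cohort.
    """

    n_low: int = 43
    n_high: int = 35
    geometry_mix: float = 29 / 78
    effect: float = 1.5
    seed: int = 0
    noise_sd: float = 0.5
    perturbation_mm: float = 2.0  # manual-delineation stand-in amplitude
    # within-class distributions of the per-subject lesion parameters
    radius_range_mm: tuple[float, float] = (8.0, 13.0)
    core_mean: float = 10.0
    core_sd: float = 1.0
    heterogeneity_mean: float = 1.0
    heterogeneity_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("need at least one subject per class")
        if not 0.0 <= self.geometry_mix <= 1.0:
            raise ValueError("geometry_mix must be in [0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


@dataclass
class ScanCase:
    """One subject: volume, spacing, truth mask, label and identifier."""

    subject_id: str
    image: np.ndarray
    spacing: tuple[float, float, float]
    truth_mask: np.ndarray
    label: str  # "low" | "high"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("mask grid must equal image grid")
        if not self.truth_mask.any():
            raise ValueError("truth mask is empty")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite intensities")


def _coordinate_fields(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec, seed: int) -> ScanCase:
    """Generate one phantom: ellipsoidal two-level lesion plus texture and noise.

    The lesion has a core/rim intensity profile (core within
    ``core_fraction`` of the normalized radius).  Intra-lesion texture is a
    Gaussian random field smoothed to a correlation length of twice the mean
    voxel spacing and scaled to unit standard deviation before multiplication
    by ``heterogeneity_amplitude``.  Identical ``(spec, seed)`` yields a
    bit-identical case.
    """
    rng = np.random.default_rng(seed)
    xs = _coordinate_fields(spec.grid_shape, spec.spacing)
    center = spec.center_mm
    r = np.sqrt(
        sum(((x - c) / rad) ** 2 for x, c, rad in zip(xs, center, spec.lesion_radii))
    )
    truth = r <= 1.0
    image = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    image[truth] = spec.rim_intensity
    image[r <= spec.core_fraction] = spec.core_intensity

    if spec.heterogeneity_amplitude > 0:
        mean_sp = float(np.mean(spec.spacing))
        sigma_vox = [2.0 * mean_sp / s for s in spec.spacing]
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(spec.grid_shape), sigma=sigma_vox, mode="reflect"
        )
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        image[truth] += spec.heterogeneity_amplitude * field_[truth]

    if spec.noise_sd > 0:
        noise = rng.standard_normal(spec.grid_shape)
        if spec.noise_fwhm_mm > 0:
            # reconstructed emission images carry spatially correlated noise;
            # emulate it by smoothing white noise to the stated FWHM
            sigma_vox = [
                spec.noise_fwhm_mm / 2.3548 / s for s in spec.spacing
            ]
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
            sd = noise.std()
            if sd > 0:
                noise /= sd
        image += spec.noise_sd * noise

    return ScanCase(
        subject_id=f"phantom-{seed}",
        image=image,
        spacing=spec.spacing,
        truth_mask=truth,
        label="low",
        params={"spec": spec, "seed": seed},
    )


def perturb_mask(
    mask: np.ndarray,
    spacing,
    amplitude_mm: float,
    seed: int,
    smooth_mm: float = 6.0,
    max_damp: int = 3,
) -> np.ndarray:
    """Smooth random boundary displacement of a binary mask.

    Thresholds the signed Euclidean distance transform at a band-limited
    Gaussian random field scaled to RMS ``amplitude_mm``, which guarantees a
    smooth, closed perturbed surface.  The largest connected component is
    kept, so the output is connected.  Amplitude 0 returns the input
    unchanged.  If the perturbation empties the mask the amplitude is halved
    and retried ``max_damp`` times before :class:`MaskPerturbationError`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("input mask is empty")
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if amplitude_mm == 0:
        return mask.copy()

    spacing = tuple(float(s) for s in spacing)
    # signed distance: negative inside the mask
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    signed = d_out - d_in

    rng = np.random.default_rng(seed)
    sigma_vox = [smooth_mm / s for s in spacing]
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(mask.shape), sigma=sigma_vox, mode="reflect"
    )
    rms = np.sqrt(np.mean(field_**2))
    if rms == 0:
        return mask.copy()
    field_ /= rms

    # anchor: the innermost voxel of the input; a boundary displacement must
    # keep it, otherwise the perturbation has effectively destroyed the mask
    anchor = np.unravel_index(int(np.argmax(d_in)), mask.shape)
    amp = float(amplitude_mm)
    for _ in range(max_damp + 1):
        out = signed <= amp * field_
        if out[anchor]:
            labels, _ = ndimage.label(out, structure=np.ones((3, 3, 3)))
            return labels == labels[anchor]
        amp /= 2.0
    raise MaskPerturbationError(
        f"perturbation of amplitude {amplitude_mm} mm emptied the mask "
        f"even after {max_damp} dampings"
    )


def _truncated_normal(rng, mean, sd, low, size=None):
    """Normal draw truncated below at ``low`` by redrawing (vector-safe)."""
    x = rng.normal(mean, sd, size=size)
    bad = x <= low
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = x <= low
    return x


def generate_cohort(spec: CohortSpec) -> list[ScanCase]:
    """Generate the full labelled cohort.

    Exactly ``n_low + n_high`` cases with the requested label proportions and
    geometry split.  High-grade subjects have their heterogeneity amplitude
    shifted upward by ``effect`` within-class standard deviations; all other
    lesion parameters are drawn from the shared within-class distributions.
    Deterministic in ``spec`` (including its ``seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_low + spec.n_high
    labels = ["low"] * spec.n_low + ["high"] * spec.n_high
    n_ge = int(round(spec.geometry_mix * n_total))
    geometries = [GEOMETRY_GE] * n_ge + [GEOMETRY_SIEMENS] * (n_total - n_ge)
    rng.shuffle(geometries)

    cases: list[ScanCase] = []
    for i, label in enumerate(labels):
        geometry = geometries[i]
        grid = _GRID_FOR_GEOMETRY.get(geometry, (40, 40, 30))
        base_radius = rng.uniform(*spec.radius_range_mm)
        radii = tuple(base_radius * (1.0 + rng.uniform(-0.15, 0.15)) for _ in range(3))
        core = _truncated_normal(rng, spec.core_mean, spec.core_sd, 2.0)
        het_mean = spec.heterogeneity_mean + (
            spec.effect * spec.heterogeneity_sd if label == "high" else 0.0
        )
        het = _truncated_normal(rng, het_mean, spec.heterogeneity_sd, 0.0)
        # jitter the lesion centre by up to one voxel; keeps the lesion inside
        extent = [n * s for n, s in zip(grid, geometry)]
        center = tuple(
            e / 2.0 + rng.uniform(-s, s) for e, s in zip(extent, geometry)
        )
        phantom_spec = PhantomSpec(
            grid_shape=grid,
            spacing=geometry,
            lesion_center=center,
            lesion_radii=radii,
            core_intensity=float(core),
            rim_intensity=0.6 * float(core),
            background_intensity=1.0,
            noise_sd=spec.noise_sd,
            heterogeneity_amplitude=float(het),
        )
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = generate_phantom(phantom_spec, seed=case_seed)
        case.subject_id = f"S{i + 1:03d}"
        case.label = label
        case.params.update(
            {
                "base_radius_mm": base_radius,
                "core_intensity": float(core),
                "heterogeneity_amplitude": float(het),
                "geometry": geometry,
            }
        )
        cases.append(case)
    return cases
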