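"""Preprocessing chain for feature extraction.

Fixed order: intensity normalization -> isotropic resampling -> derived
images (identity, Laplacian-of-Gaussian at 10 scales, 8 single-level
undecimated 3D wavelet sub-bands) -> per-image fixed-bin-width
discretization inside the mask.

Conventions that change values and are therefore fixed here:

* normalization uses the population (n-denominator) standard deviation;
* LoG and wavelet filtering use symmetric boundary extension;
* wavelet sub-band labels are the per-axis filter sequence in (x, y, z)
  order, H = high-pass, L = low-pass;
* discretization anchors bin 1 at the masked minimum of each derived image
  independently, with a fixed bin width.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ExtractionConfig",
    "DerivedImage",
    "SUBBAND_LABELS",
    "normalize_image",
    "resample_to_isotropic",
    "log_filter",
    "wavelet_subbands",
    "wavelet_reconstruct",
    "discretize",
    "derive_images",
]

#: All 8 per-axis filter sequences, axis order (x, y, z).
SUBBAND_LABELS = tuple(
    "".join(c) for c in itertools.product("HL", repeat=3)
)  # HHH ... LLL

_DEFAULT_SIGMAS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings (defaults follow the reference configuration)."""

    bin_width: float = 0.25
    resample_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    wavelet_name: str = "coif1"
    log_sigmas: tuple[float, ...] = _DEFAULT_SIGMAS
    normalization_enabled: bool = True
    normalization_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("log sigmas must be > 0")
        if any(s <= 0 for s in self.resample_spacing):
            raise ValueError("resample spacing must be > 0")

    @property
    def n_derived(self) -> int:
        # original + LoG scales + wavelet sub-bands
        return 1 + len(self.log_sigmas) + 8


@dataclass
class DerivedImage:
    """A filtered volume with its identifying label (e.g. ``wavelet_LLL``)."""

    volume: np.ndarray
    label: str
    kind: str  # "original" | "log" | "wavelet"
    parameter: str | float | None = None


def normalize_image(image: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Whole-volume z-scoring times ``scale`` (population SD)."""
    image = np.asarray(image, dtype=np.float64)
    sd = image.std()
    if sd == 0:
        raise ValueError("cannot normalize an image with zero intensity variance")
    return (image - image.mean()) / sd * scale


def _to_sitk(array: np.ndarray, spacing) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK expects (z, y, x) buffers
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def resample_to_isotropic(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    target_spacing=(2.0, 2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Resample image (cubic B-spline) and mask (nearest) onto a new grid."""
    mask = np.asarray(mask, dtype=np.uint8)
    if not mask.any():
        raise ValueError("mask is empty before resampling")
    size = [
        max(1, int(np.ceil(n * s / t)))
        for n, s, t in zip(image.shape, spacing, target_spacing)
    ]
    ref = sitk.Image(size, sitk.sitkFloat64)
    ref.SetSpacing(tuple(float(t) for t in target_spacing))

    def run(arr, interp, default):
        res = sitk.Resample(
            _to_sitk(arr, spacing),
            ref,
            sitk.Transform(),
            interp,
            float(default),
            sitk.sitkFloat64,
        )
        return _from_sitk(res)

    out_img = run(np.asarray(image, dtype=np.float64), sitk.sitkBSpline, image.min())
    out_mask = run(mask.astype(np.float64), sitk.sitkNearestNeighbor, 0) > 0.5
    if not out_mask.any():
        raise ValueError("mask became empty after resampling")
    return out_img, out_mask


def log_filter(image: np.ndarray, sigma_mm: float, spacing) -> DerivedImage:
    """Scale-normalized Laplacian-of-Gaussian response at scale ``sigma_mm``.

    Sigma is specified in mm and converted to voxels via the spacing; the
    response is multiplied by sigma^2 (scale normalization), so a constant
    image maps to exactly zero and blob responses are comparable across
    scales.
    """
    sigma_vox = [sigma_mm / float(s) for s in spacing]
    if min(sigma_vox) < 0.5:
        import warnings

        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half a voxel for spacing {spacing}; "
            "response is dominated by the discrete grid",
            stacklevel=2,
        )
    image = np.asarray(image, dtype=np.float64)
    raw = ndimage.gaussian_laplace(image, sigma=sigma_vox, mode="reflect")
    # the truncated discrete kernel has a small nonzero DC gain; remove it so
    # a constant image maps to exactly zero
    probe = np.ones((3, 3, 3))
    dc = float(ndimage.gaussian_laplace(probe, sigma=sigma_vox, mode="reflect")[1, 1, 1])
    resp = sigma_mm**2 * (raw - dc * image)
    slab = f"{sigma_mm:g}".replace(".", "_")
    return DerivedImage(resp, f"log_sigma_{slab}", "log", sigma_mm)


def _band_filters(wavelet_name: str):
    w = pywt.Wavelet(wavelet_name)
    return {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}


def _swt3(image: np.ndarray, wavelet_name: str, pad: int | None = None):
    """Undecimated single-level 3D transform with symmetric boundary.

    Implemented as symmetric padding by ``pad`` voxels followed by periodic
    correlation per axis and cropping; for pad >= filter length this equals
    symmetric-extension filtering while keeping the transform exactly
    invertible on the padded domain.  Returns (padded bands, pad).
    """
    filters = _band_filters(wavelet_name)
    flen = len(filters["L"])
    if pad is None:
        pad = flen + 2
    x = np.pad(np.asarray(image, dtype=np.float64), pad, mode="symmetric")
    bands = {}
    for label in SUBBAND_LABELS:
        out = x
        for axis, letter in enumerate(label):
            out = ndimage.correlate1d(out, filters[letter], axis=axis, mode="wrap")
        bands[label] = out
    return bands, pad


def wavelet_subbands(
    image: np.ndarray, wavelet_name: str = "coif1"
) -> list[DerivedImage]:
    """The 8 sub-bands of a single-level undecimated 3D decomposition.

    Output grids equal the input grid.  Any band containing at least one
    high-pass factor is identically zero on a constant image.
    """
    bands, pad = _swt3(image, wavelet_name)
    crop = tuple(slice(pad, pad + n) for n in image.shape)
    return [
        DerivedImage(bands[label][crop], f"wavelet_{label}", "wavelet", label)
        for label in SUBBAND_LABELS
    ]


def wavelet_reconstruct(image: np.ndarray, wavelet_name: str = "coif1") -> np.ndarray:
    """Round-trip the undecimated transform (perfect-reconstruction check).

    Decomposes ``image`` and re-synthesizes it from the 8 sub-bands on the
    padded domain (convolution with the same orthonormal filters, divided by
    2 per axis), then crops.  For an orthonormal wavelet the result equals
    the input to numerical precision.
    """
    bands, pad = _swt3(image, wavelet_name)
    filters = _band_filters(wavelet_name)
    recon = np.zeros_like(next(iter(bands.values())))
    for label, band in bands.items():
        out = band
        for axis, letter in enumerate(label):
            out = ndimage.convolve1d(out, filters[letter], axis=axis, mode="wrap")
        recon += out
    recon /= 8.0
    crop = tuple(slice(pad, pad + n) for n in image.shape)
    return recon[crop]


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels: floor((x - min)/w) + 1 (levels >= 1)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("no values to discretize")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return levels


def derive_images(
    image: np.ndarray, spacing, config: ExtractionConfig
) -> list[DerivedImage]:
    """Original + 10 LoG + 8 wavelet images, in a fixed, labelled order."""
    out = [DerivedImage(np.asarray(image, dtype=np.float64), "original", "original")]
    for sigma in config.log_sigmas:
        out.append(log_filter(image, sigma, spacing))
    out.extend(wavelet_subbands(image, config.wavelet_name))
    return out
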