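"""Filter bank producing the 12 derived images per MRI sequence.

Beyond the original volume, each sequence yields exactly 12 derived images:

* 4 wavelet subbands (LL, LH, HL, HH) — single-level undecimated 2D wavelet
  transform applied slice-wise along the third array axis,
* 4 Laplacian-of-Gaussian responses at σ = 2, 3, 4, 5 mm (σ given in
  millimetres and converted to voxel units via the spacing),
* 4 pointwise intensity transforms (square, square root, logarithm,
  exponential) with range-preserving rescaling.

Intensity (first-order and texture) features are extracted from the original
and all 12 derived images; shape features only ever see the ROI geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

#: canonical image-type order: original + the 12 derived types
IMAGE_TYPES = (
    "original",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
    "log-sigma-2",
    "log-sigma-3",
    "log-sigma-4",
    "log-sigma-5",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
)

DERIVED_TYPES = IMAGE_TYPES[1:]


@dataclass
class DerivedImage:
    voxels: np.ndarray
    image_type: str

    def __post_init__(self):
        # LoG tags at non-default scales (e.g. log-sigma-1.5) are legal
        if self.image_type not in IMAGE_TYPES and not self.image_type.startswith("log-sigma-"):
            raise ValueError(f"unknown image type {self.image_type!r}")


def _check_volume(volume: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {volume.ndim}D")
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite voxels")
    return volume


def _gauss_kernels(sigma: float, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Analytically sampled 1D Gaussian and its second derivative."""
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2)) / (np.sqrt(2.0 * np.pi) * sigma)
    g2 = g * (x ** 2 - sigma ** 2) / sigma ** 4
    return g, g2


def log_filter(volume, spacing_mm, sigma_mm: float) -> DerivedImage:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    The scale is isotropic in millimetres; per-axis voxel sigmas are
    ``sigma_mm / spacing``. The Laplacian splits into three separable
    convolutions with analytically sampled 1D kernels (so the impulse
    response equals the analytic 3D LoG kernel at grid points); boundaries
    are mirror-padded and kernels truncated at 7σ.
    """
    volume = _check_volume(volume)
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    spacing = np.asarray(spacing_mm, dtype=float)
    if sigma_mm < 0.5 * spacing.max():
        warnings.warn(
            f"LoG scale {sigma_mm} mm is below half the voxel size "
            f"{spacing.max()} mm; response is under-resolved",
            stacklevel=2,
        )
    sigma_vox = sigma_mm / spacing
    kernels, pads = [], []
    for ax in range(3):
        radius = int(np.ceil(7.0 * sigma_vox[ax]))
        kernels.append(_gauss_kernels(sigma_vox[ax], radius))
        # reflect-pad axes shorter than the kernel radius so truncation
        # error stays below the sampled-kernel precision
        pads.append((max(0, radius - (volume.shape[ax] - 1)),) * 2)
    padded = np.pad(volume, pads, mode="reflect") if any(p[0] for p in pads) else volume
    out = np.zeros_like(padded)
    for deriv_ax in range(3):
        term = padded
        for ax in range(3):
            g, g2 = kernels[ax]
            k = g2 if ax == deriv_ax else g
            term = ndimage.correlate1d(term, k, axis=ax, mode="mirror")
        out += term
    if padded is not volume:
        sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pads, volume.shape))
        out = out[sl]
    tag = f"log-sigma-{int(sigma_mm) if float(sigma_mm).is_integer() else sigma_mm}"
    return DerivedImage(voxels=out, image_type=tag)


def wavelet_subbands(volume, wavelet: str = "coif1") -> list[DerivedImage]:
    """Single-level undecimated 2D wavelet subbands, slice-wise.

    The 2D transform runs on the first two array axes of every slice along
    the third axis, yielding four full-size subband volumes tagged
    LL (approximation), LH, HL and HH. Odd slice dimensions are edge-padded
    to even before the stationary transform and cropped back.
    """
    volume = _check_volume(volume)
    n0, n1, n2 = volume.shape
    p0, p1 = n0 % 2, n1 % 2
    out = {tag: np.empty_like(volume) for tag in ("LL", "LH", "HL", "HH")}
    for k in range(n2):
        sl = volume[:, :, k]
        if p0 or p1:
            sl = np.pad(sl, ((0, p0), (0, p1)), mode="edge")
        (cA, (cH, cV, cD)) = pywt.swt2(sl, wavelet, level=1, norm=False)[0]
        for tag, band in zip(("LL", "LH", "HL", "HH"), (cA, cH, cV, cD)):
            out[tag][:, :, k] = band[:n0, :n1]
    return [DerivedImage(voxels=out[t], image_type=f"wavelet-{t}") for t in ("LL", "LH", "HL", "HH")]


def intensity_transforms(volume) -> list[DerivedImage]:
    """Pointwise square / square-root / logarithm / exponential transforms.

    Each transform rescales so the output's maximum absolute value equals the
    input's, making the four images comparable under a common discretization
    bin width. All are monotone non-decreasing on the input range. An
    all-zero volume maps to all-zero outputs (degenerate scaling = identity).
    """
    volume = _check_volume(volume)
    m = float(np.abs(volume).max())
    if m == 0.0:
        z = np.zeros_like(volume)
        return [DerivedImage(z.copy(), t) for t in ("square", "squareroot", "logarithm", "exponential")]

    square = (volume / np.sqrt(m)) ** 2 * np.sign(volume)
    squareroot = np.sign(volume) * np.sqrt(np.abs(volume) * m)
    logarithm = np.sign(volume) * np.log(np.abs(volume) + 1.0)
    lm = float(np.abs(logarithm).max())
    if lm > 0:
        logarithm = logarithm * (m / lm)
    exponential = np.exp(volume * (np.log(m) / m))
    return [
        DerivedImage(square, "square"),
        DerivedImage(squareroot, "squareroot"),
        DerivedImage(logarithm, "logarithm"),
        DerivedImage(exponential, "exponential"),
    ]


def derive_images(volume, spacing_mm, wavelet: str = "coif1",
                  log_sigmas_mm=(2.0, 3.0, 4.0, 5.0)) -> list[DerivedImage]:
    """All 12 derived images in canonical order (wavelets, LoG, pointwise)."""
    volume = _check_volume(volume)
    images = wavelet_subbands(volume, wavelet=wavelet)
    for s in log_sigmas_mm:
        images.append(log_filter(volume, spacing_mm, s))
    images.extend(intensity_transforms(volume))
    assert [im.image_type for im in images] == list(DERIVED_TYPES)
    return images
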