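"""Pseudo-clinical CT synthesis: downsample, project, add noise, backproject.

A high-resolution (micro-CT-surrogate) volume is degraded slice by slice:
each axial slice is forward-projected into parallel-beam sinogram space,
i.i.d. zero-mean Gaussian noise is added to the sinogram, and the slice is
reconstructed by filtered backprojection (ramp filter).  This reproduces the
character of clinical CT noise — correlated reconstruction noise and streaks —
rather than plain image-domain noise.

Three named presets emulate next-generation cone-beam CT (0.15 mm voxels),
standard multidetector CT (0.3 mm) and poor multidetector CT (0.45 mm).
Noise levels are expressed as a fraction of the sinogram dynamic range; only
their relative ordering is meaningful, and the preset amplitudes follow the
relative 60/70/75 dB ordering of the three conditions
(ratios 10**((dB-60)/20)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

from .errors import FormatError, ParameterError
from .volume import Volume

_BASE_NOISE = 0.004  # fraction of sinogram dynamic range at the 60 dB setting

PRESETS = {
    "cbct": {"target_spacing": 0.15, "noise_sigma": _BASE_NOISE},
    "mdct": {"target_spacing": 0.30, "noise_sigma": _BASE_NOISE * 10 ** (10 / 20)},
    "poor_mdct": {"target_spacing": 0.45, "noise_sigma": _BASE_NOISE * 10 ** (15 / 20)},
}


@dataclass(frozen=True)
class DegradeConfig:
    target_spacing: float
    noise_sigma: float
    n_projection_angles: int | None = None  # None: 1.5x the Nyquist criterion
    preset_name: str | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.target_spacing <= 0 or not np.isfinite(self.target_spacing):
            raise ParameterError("target_spacing must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if self.n_projection_angles is not None and self.n_projection_angles < 2:
            raise ParameterError("need at least 2 projection angles")

    @staticmethod
    def from_preset(name: str, rng_seed: int = 0) -> "DegradeConfig":
        if name not in PRESETS:
            raise ParameterError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return DegradeConfig(preset_name=name, rng_seed=rng_seed, **PRESETS[name])


def nyquist_angles(width: int, factor: float = 1.5) -> int:
    """Projection count: ``factor`` times the parallel-beam Nyquist criterion."""
    return max(2, int(np.ceil(factor * np.pi / 2 * width)))


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample(vol: Volume, target_spacing: float) -> Volume:
    """Anti-aliased resampling to a coarser isotropic grid.

    Integer spacing ratios use exact block averaging; other ratios use a
    Gaussian anti-alias filter followed by linear interpolation.  The world
    extent is preserved to within one target voxel.
    """
    if target_spacing < vol.spacing - 1e-12:
        raise ParameterError(
            f"target spacing {target_spacing} mm is finer than source "
            f"{vol.spacing} mm: upsampling is not supported")
    if abs(target_spacing - vol.spacing) < 1e-12:
        return vol.copy()
    ratio = target_spacing / vol.spacing
    data = np.asarray(vol.data, float)
    if abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        n_new = [s // f for s in vol.shape]
        trimmed = data[: n_new[0] * f, : n_new[1] * f, : n_new[2] * f]
        block = trimmed.reshape(n_new[0], f, n_new[1], f, n_new[2], f)
        out = block.mean(axis=(1, 3, 5))
        origin = vol.origin + (f - 1) / 2 * vol.spacing
        return Volume(out, target_spacing, origin)
    sigma = np.sqrt(max(ratio ** 2 - 1.0, 0.0)) / 2.0
    smooth = ndimage.gaussian_filter(data, sigma, mode="nearest")
    n_new = [max(2, int(np.floor((s - 1) / ratio)) + 1) for s in vol.shape]
    coords = np.meshgrid(*[np.arange(n) * ratio for n in n_new], indexing="ij")
    out = ndimage.map_coordinates(smooth, np.array(coords), order=1, mode="nearest")
    return Volume(out, target_spacing, vol.origin.copy())


# ---------------------------------------------------------------------------
# sinogram domain
# ---------------------------------------------------------------------------

@dataclass
class Sinogram:
    data: np.ndarray                 # (n_detectors, n_angles)
    theta_deg: np.ndarray            # projection angles in [0, 180)
    image_shape: tuple               # original (possibly non-square) slice shape
    pad: tuple = ((0, 0), (0, 0))    # padding applied before projection
    pad_value: float = 0.0


def project_slice(slice2d: np.ndarray, n_angles: int | None = None) -> Sinogram:
    """Parallel-beam line-integral projection over angles uniform in [0, 180)."""
    img = np.asarray(slice2d, float)
    if img.ndim != 2:
        raise ParameterError("slice must be 2-D")
    if n_angles is None:
        n_angles = nyquist_angles(max(img.shape))
    if n_angles < 2:
        raise ParameterError("need at least 2 projection angles")
    n = max(img.shape)
    pad = ((0, n - img.shape[0]), (0, n - img.shape[1]))
    pad_value = float(img.min())
    padded = np.pad(img, pad, constant_values=pad_value)
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(padded, theta=theta, circle=False)
    return Sinogram(data=sino, theta_deg=theta, image_shape=img.shape,
                    pad=pad, pad_value=pad_value)


def add_detector_noise(sino: Sinogram, sigma: float, seed: int,
                       dynamic_range: float | None = None) -> Sinogram:
    """Add i.i.d. zero-mean Gaussian noise, std ``sigma`` x dynamic range."""
    if sigma < 0:
        raise ParameterError("noise sigma must be non-negative")
    if sigma == 0:
        return Sinogram(sino.data.copy(), sino.theta_deg, sino.image_shape,
                        sino.pad, sino.pad_value)
    if dynamic_range is None:
        dynamic_range = float(sino.data.max() - sino.data.min())
    rng = np.random.default_rng(seed)
    noisy = sino.data + rng.normal(0.0, sigma * dynamic_range, sino.data.shape)
    return Sinogram(noisy, sino.theta_deg, sino.image_shape, sino.pad,
                    sino.pad_value)


def reconstruct_slice(sino: Sinogram, theta_deg: np.ndarray | None = None) -> np.ndarray:
    """Filtered backprojection (ramp filter) back onto the projected grid."""
    if theta_deg is not None and (len(theta_deg) != len(sino.theta_deg)
                                  or not np.allclose(theta_deg, sino.theta_deg)):
        raise FormatError("projection angles do not match the sinogram")
    n = max(sino.image_shape)
    rec = iradon(sino.data, theta=sino.theta_deg, circle=False,
                 filter_name="ramp", output_size=n)
    return rec[: sino.image_shape[0], : sino.image_shape[1]]


# ---------------------------------------------------------------------------
# full volume degradation
# ---------------------------------------------------------------------------

def degrade_volume(vol: Volume, cfg: DegradeConfig) -> Volume:
    """Downsample, then per-axial-slice project -> noise -> reconstruct.

    The sinogram dynamic range used to scale the noise is computed globally
    over the volume so every slice receives the same absolute noise level.
    """
    ds = downsample(vol, cfg.target_spacing)
    n_angles = cfg.n_projection_angles or nyquist_angles(max(ds.shape[:2]))
    sinos = [project_slice(ds.data[:, :, k], n_angles) for k in range(ds.shape[2])]
    lo = min(float(s.data.min()) for s in sinos)
    hi = max(float(s.data.max()) for s in sinos)
    dyn = hi - lo
    rng = np.random.default_rng(cfg.rng_seed)
    out = np.empty(ds.shape, float)
    for k, s in enumerate(sinos):
        noisy = add_detector_noise(s, cfg.noise_sigma,
                                   seed=int(rng.integers(2 ** 31 - 1)),
                                   dynamic_range=dyn)
        out[:, :, k] = reconstruct_slice(noisy)
    return Volume(out, ds.spacing, ds.origin.copy())
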