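"""Synthetic BF tomogram phantoms with known ground truth.

The generator emulates the statistical structure the density analysis
assumes: an ellipsoidal mitochondrion in cytosol, spherical matrix granules
of known fraction-of-TCP density, ribosome-like puncta as internal
standards, and a BF intensity model

    I = background_x - contrast_gain * S(r),

with S the local scattering signal (nm^-1), followed by a Gaussian PSF and
additive Gaussian noise. Because the same linear model underlies the
calibration, a phantom provides exact ground truth for end-to-end parameter
recovery: measure intensity levels from the ground-truth masks, calibrate,
and compare recovered densities and volume fractions against the generator
inputs.

All randomness flows from the single ``seed`` in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from cstetquant.calibration import (
    IntensityCalibration,
    ThresholdSet,
    density_fraction,
)
from cstetquant.morphometry import VolumeGrid

#: Unrounded reference signals (nm^-1) from the packaged tables; kept as
#: module constants so a spec is self-contained once constructed.
WATER_SIGNAL = 0.158534
RIBOSOME_SIGNAL = 0.249240
TCP_SIGNAL = 0.963233


def _default_signals() -> dict[str, float]:
    """Recompute default signals from the packaged reference tables."""
    from cstetquant.composition import reference_profiles
    from cstetquant.scattering import load_cross_sections, signal_per_volume

    profiles = reference_profiles()
    xsec = load_cross_sections()
    return {
        name: signal_per_volume(profiles[name], xsec).signal
        for name in ("water", "ribosome", "tcp")
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic BF tomogram.

    Geometry in nm; intensities in tomogram units. Defaults describe a
    512 nm cube (256^3 voxels at 2 nm) holding one mitochondrion whose
    granules occupy 20% of its volume at 40% of crystalline-TCP density,
    with granule diameters lognormal between 20 and 100 nm — the regime the
    analysis is designed for.
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size: float = 2.0

    mito_semi_axes: tuple[float, float, float] = (200.0, 220.0, 240.0)  # z, y, x nm
    mito_center: tuple[float, float, float] | None = None  # nm; None = grid center

    n_granules: int | None = None  # None: fill-driven
    target_fill: float | None = 0.20
    granule_diameter_median: float = 50.0  # nm
    granule_diameter_sigma: float = 0.35  # lognormal sigma of ln(d)
    granule_diameter_range: tuple[float, float] = (20.0, 100.0)
    granule_fraction_of_tcp: float | tuple[float, float] = 0.40

    n_ribosomes: int = 300
    ribosome_diameter: float = 25.0  # nm

    cytosol_signal: float = WATER_SIGNAL  # nm^-1
    matrix_signal: float = WATER_SIGNAL
    ribosome_signal: float = RIBOSOME_SIGNAL
    tcp_signal: float = TCP_SIGNAL

    background_x: float = 24.3
    water_level: float = 16.0  # implied intensity of pure-water regions
    contrast_gain: float | None = None  # None: derived from water_level

    psf_sigma: float = 2.0  # nm
    noise_sd: float = 1.0  # intensity units
    seed: int = 0

    max_placement_attempts: int = 20000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or self.voxel_size <= 0:
            raise ValueError("grid shape and voxel size must be positive")
        if any(a <= 0 for a in self.mito_semi_axes):
            raise ValueError("mitochondrion semi-axes must be positive")
        lo, hi = self.granule_diameter_range
        if not 0 < lo < hi:
            raise ValueError("granule diameter range must satisfy 0 < lo < hi")
        if self.target_fill is not None and not 0 <= self.target_fill < 1:
            raise ValueError("target_fill must be in [0, 1)")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be non-negative")
        if self.background_x <= self.water_level:
            raise ValueError("background must exceed the water level (BF polarity)")

    @property
    def gain(self) -> float:
        """Contrast gain (intensity per nm^-1 of signal)."""
        if self.contrast_gain is not None:
            return self.contrast_gain
        return (self.background_x - self.water_level) / self.cytosol_signal

    def intensity_of_signal(self, signal: float) -> float:
        """Noise-free intensity a region of the given signal would take."""
        return self.background_x - self.gain * signal

    def implied_calibration(self) -> IntensityCalibration:
        """The exact calibration the phantom encodes (for oracle use)."""
        return IntensityCalibration(
            background_x=self.background_x,
            water_intensity=self.intensity_of_signal(self.cytosol_signal),
            tcp_intensity=self.intensity_of_signal(self.tcp_signal),
            tcp_water_ratio=self.tcp_signal / self.cytosol_signal,
            reference_used="ground_truth",
        )


@dataclass
class PhantomResult:
    """A generated phantom: volume, ground truth and object masks."""

    volume: VolumeGrid
    granules: pd.DataFrame  # z, y, x (nm), diameter_nm, fraction_of_tcp
    masks: Mapping[str, np.ndarray]  # mitochondrion, granules, ribosomes (labels)
    realized_fill: float  # granule voxels / mitochondrion voxels
    spec: PhantomSpec


class PackingError(RuntimeError):
    """Raised when the requested granule fill cannot be packed."""


def _truncated_lognormal(rng, median, sigma, lo, hi, max_tries=1000) -> float:
    for _ in range(max_tries):
        d = rng.lognormal(np.log(median), sigma)
        if lo <= d <= hi:
            return float(d)
    raise PackingError(
        f"could not draw a diameter in [{lo}, {hi}] from "
        f"lognormal(median={median}, sigma={sigma})"
    )


def _place_granules(spec: PhantomSpec, rng) -> pd.DataFrame:
    """Rejection-sample non-overlapping spheres inside the ellipsoid."""
    center = np.asarray(
        spec.mito_center
        if spec.mito_center is not None
        else [s * spec.voxel_size / 2.0 for s in spec.shape]
    )
    axes = np.asarray(spec.mito_semi_axes)
    ellipsoid_volume = 4.0 / 3.0 * np.pi * np.prod(axes)
    lo, hi = spec.granule_diameter_range

    centers: list[np.ndarray] = []
    radii: list[float] = []
    fractions: list[float] = []
    total_volume = 0.0
    attempts = 0

    def done() -> bool:
        if spec.target_fill is not None:
            return total_volume / ellipsoid_volume >= spec.target_fill
        return len(radii) >= (spec.n_granules or 0)

    while not done():
        if attempts >= spec.max_placement_attempts:
            raise PackingError(
                f"placed {len(radii)} granules "
                f"(fill {total_volume / ellipsoid_volume:.3f}) after "
                f"{attempts} attempts; requested packing is infeasible"
            )
        attempts += 1
        d = _truncated_lognormal(rng, spec.granule_diameter_median,
                                 spec.granule_diameter_sigma, lo, hi)
        r = d / 2.0
        inner = axes - r
        if np.any(inner <= 0):
            continue
        # uniform in the bounding box of the shrunken ellipsoid, accept inside
        c = center + (rng.uniform(-1, 1, size=3)) * inner
        if np.sum(((c - center) / inner) ** 2) > 1.0:
            continue
        if centers:
            dist = np.linalg.norm(np.asarray(centers) - c, axis=1)
            if np.any(dist < np.asarray(radii) + r):
                continue
        centers.append(c)
        radii.append(r)
        f = spec.granule_fraction_of_tcp
        if isinstance(f, tuple):
            f = float(rng.uniform(*f))
        fractions.append(float(f))
        total_volume += 4.0 / 3.0 * np.pi * r**3

    if not centers:
        return pd.DataFrame(
            columns=["z", "y", "x", "diameter_nm", "fraction_of_tcp"]
        )
    arr = np.asarray(centers)
    return pd.DataFrame(
        {
            "z": arr[:, 0],
            "y": arr[:, 1],
            "x": arr[:, 2],
            "diameter_nm": 2.0 * np.asarray(radii),
            "fraction_of_tcp": fractions,
        }
    )


def _place_ribosomes(spec: PhantomSpec, rng) -> pd.DataFrame:
    """Scatter non-overlapping ribosome spheres in the cytosol."""
    v = spec.voxel_size
    r = spec.ribosome_diameter / 2.0
    extent = np.asarray(spec.shape) * v
    center = np.asarray(
        spec.mito_center
        if spec.mito_center is not None
        else extent / 2.0
    )
    axes = np.asarray(spec.mito_semi_axes) + r
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_ribosomes:
        if attempts >= spec.max_placement_attempts:
            raise PackingError(
                f"placed {len(centers)}/{spec.n_ribosomes} ribosomes after "
                f"{attempts} attempts"
            )
        attempts += 1
        c = rng.uniform(r, extent - r)
        if np.sum(((c - center) / axes) ** 2) <= 1.0:
            continue  # inside (or touching) the mitochondrion
        if centers:
            dist = np.linalg.norm(np.asarray(centers) - c, axis=1)
            if np.any(dist < 2 * r):
                continue
        centers.append(c)
    if not centers:
        return pd.DataFrame(columns=["z", "y", "x", "diameter_nm"])
    arr = np.asarray(centers)
    return pd.DataFrame(
        {"z": arr[:, 0], "y": arr[:, 1], "x": arr[:, 2],
         "diameter_nm": spec.ribosome_diameter}
    )


def _paint_spheres(
    labels: np.ndarray,
    table: pd.DataFrame,
    voxel_size: float,
) -> None:
    """Rasterize spheres into an integer label array (1-based row order)."""
    shape = labels.shape
    for i, row in enumerate(table.itertuples(index=False), start=1):
        c = np.array([row.z, row.y, row.x]) / voxel_size - 0.5
        r_vox = row.diameter_nm / 2.0 / voxel_size
        lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        inside = (
            (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ) <= r_vox**2
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = i


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom tomogram; deterministic for a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    v = spec.voxel_size
    shape = spec.shape
    extent = np.asarray(shape) * v
    center = np.asarray(
        spec.mito_center if spec.mito_center is not None else extent / 2.0
    )
    axes = np.asarray(spec.mito_semi_axes)

    # voxel-center coordinates in nm
    coords = [
        (np.arange(n) + 0.5) * v for n in shape
    ]
    zz = ((coords[0] - center[0]) / axes[0]) ** 2
    yy = ((coords[1] - center[1]) / axes[1]) ** 2
    xx = ((coords[2] - center[2]) / axes[2]) ** 2
    mito_mask = (
        zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    ) <= 1.0

    granules = _place_granules(spec, rng)
    granule_labels = np.zeros(shape, dtype=np.int32)
    _paint_spheres(granule_labels, granules, v)

    ribosomes = _place_ribosomes(spec, rng)
    ribosome_labels = np.zeros(shape, dtype=np.int32)
    _paint_spheres(ribosome_labels, ribosomes, v)

    signal = np.full(shape, spec.cytosol_signal, dtype=np.float32)
    signal[mito_mask] = spec.matrix_signal
    signal[ribosome_labels > 0] = spec.ribosome_signal
    if len(granules):
        fr = np.concatenate(
            [[0.0], granules["fraction_of_tcp"].to_numpy()]
        ).astype(np.float32)
        in_granule = granule_labels > 0
        signal[in_granule] = fr[granule_labels[in_granule]] * spec.tcp_signal

    intensity = spec.background_x - spec.gain * signal
    if spec.psf_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.psf_sigma / v)
    if spec.noise_sd > 0:
        intensity = intensity + spec.noise_sd * rng.standard_normal(
            shape, dtype=np.float32
        )

    n_mito = int(mito_mask.sum())
    realized_fill = (
        float(((granule_labels > 0) & mito_mask).sum()) / n_mito if n_mito else 0.0
    )
    volume = VolumeGrid(intensity.astype(np.float32), v, "bf")
    masks = {
        "mitochondrion": mito_mask,
        "granules": granule_labels,
        "ribosomes": ribosome_labels,
    }
    return PhantomResult(volume, granules, masks, realized_fill, spec)


# ---------------------------------------------------------------------------
# end-to-end parameter recovery


def measure_thresholds(
    result: PhantomResult,
    min_reference_diameter: float = 40.0,
    erosion_iterations: int | None = None,
) -> ThresholdSet:
    """Measure the five calibration levels from the ground-truth masks.

    ``peak`` levels are mean intensities over eroded object interiors
    (erosion strips PSF-affected boundary voxels); only granules at least
    ``min_reference_diameter`` nm wide contribute, since smaller ones never
    reach their plateau value under the PSF. ``inclusive`` levels are the
    half-contrast levels between an object interior and its surroundings —
    the level at which the blurred boundary crosses the true one for a
    symmetric PSF.
    """
    spec = result.spec
    data = result.volume.data
    v = spec.voxel_size
    if erosion_iterations is None:
        erosion_iterations = max(2, int(np.ceil(2 * spec.psf_sigma / v)) + 1)

    big = result.granules["diameter_nm"] >= min_reference_diameter
    big_ids = set(result.granules.index[big] + 1)
    gmask = np.isin(result.masks["granules"], list(big_ids))
    gcore = ndimage.binary_erosion(gmask, iterations=erosion_iterations)
    if not gcore.any():
        raise ValueError(
            "no granule interior voxels survive erosion; "
            "increase granule sizes or reduce erosion"
        )
    granule_peak = float(data[gcore].mean())

    rmask = result.masks["ribosomes"] > 0
    rcore = ndimage.binary_erosion(rmask, iterations=erosion_iterations)
    if not rcore.any():
        raise ValueError("no ribosome interior voxels survive erosion")
    ribosome_peak = float(data[rcore].mean())

    cytosol = ~result.masks["mitochondrion"] & ~ndimage.binary_dilation(
        rmask, iterations=erosion_iterations
    )
    water = float(data[cytosol].mean())

    matrix = result.masks["mitochondrion"] & ~ndimage.binary_dilation(
        result.masks["granules"] > 0, iterations=erosion_iterations
    )
    matrix_level = float(data[matrix].mean())

    granule_inclusive = matrix_level - 0.5 * (matrix_level - granule_peak)
    ribosome_inclusive = water - 0.5 * (water - ribosome_peak)
    return ThresholdSet(
        granule_peak=granule_peak,
        granule_inclusive=granule_inclusive,
        ribosome_peak=ribosome_peak,
        ribosome_inclusive=ribosome_inclusive,
        water=water,
    )


def recover_parameters(
    result: PhantomResult,
    min_reference_diameter: float = 40.0,
) -> dict:
    """Run calibration + morphometry on a phantom and compare to truth.

    The ribosome interior level is paired with the predicted whole-ribosome
    /water signal ratio (phantom ribosomes are homogeneous spheres), the TCP
    level extrapolated with the predicted TCP/water ratio, and granule
    density read off the calibrated scale. Granule volume fraction inside
    the mitochondrion is measured by segmenting at the inclusive granule
    level.

    Returns a dict with recovered and true values.
    """
    from cstetquant.morphometry import segment_by_threshold

    spec = result.spec
    thresholds = measure_thresholds(result, min_reference_diameter)
    ribosome_water = spec.ribosome_signal / spec.cytosol_signal
    tcp_water = spec.tcp_signal / spec.cytosol_signal
    calib = IntensityCalibration.from_reference(
        thresholds.ribosome_peak,
        thresholds.water,
        ribosome_water,
        tcp_water,
        reference_used="ribosome_interior",
    )
    est = density_fraction(thresholds.granule_peak, calib)

    seg = segment_by_threshold(result.volume, thresholds.granule_inclusive)
    mito = result.masks["mitochondrion"]
    recovered_fill = float((seg.foreground & mito).sum()) / float(mito.sum())

    true_fraction = result.granules["fraction_of_tcp"].mean() if len(result.granules) else np.nan
    return {
        "thresholds": thresholds,
        "calibration": calib,
        "recovered_fraction_of_tcp": est.fraction_of_tcp,
        "true_fraction_of_tcp": float(true_fraction),
        "recovered_fill": recovered_fill,
        "true_fill": result.realized_fill,
        "recovered_background": calib.background_x,
        "true_background": spec.background_x,
    }
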