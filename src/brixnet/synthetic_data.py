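"""Synthetic hyperspectral fruit scenes with a known SSC signal.

The generator emulates the statistical structure a reflectance-calibrated
fruit-imaging pipeline assumes: a roughly circular bright fruit on a dark
background, smooth visible/NIR reflectance baselines, Gaussian absorption
features whose depth grows linearly with the latent soluble-solids content
(SSC, °Brix), a smooth multiplicative illumination field, additive sensor
noise, and white/black reference cubes so that reflectance calibration is a
nontrivial step.  Every downstream stage (masking, patching, the attention
networks, evaluation) is testable against ground truth produced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as _io

__all__ = [
    "SyntheticSceneParams",
    "LabeledCube",
    "sample_ssc",
    "generate_cube",
    "generate_dataset",
    "save_dataset",
]

_DARK_COUNTS = 30.0
_GAIN_SCALE = 1000.0
_WHITE_REFLECTANCE = 0.999
_ABSORPTION_FWHM_NM = 30.0
_BUMP_CENTERS_NM = (500.0, 700.0, 900.0)
_BUMP_AMP_SD = 0.02
_BUMP_AMP_CLIP = 0.05


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Scene-generation parameters; defaults give a desk-scale 64x64x32 scene.

    ``informative_bands`` are wavelength centres (nm) where absorption depth is
    ``absorption_slope * (ssc - ssc_min)`` reflectance units, so the calibrated
    fruit reflectance there decreases linearly with SSC.  The SSC population
    follows the reference distribution of a 570-apple survey: Normal(11.76,
    1.92²) °Brix, rejection-clipped to [7.2, 18.1].
    """

    n_rows: int = 64
    n_cols: int = 64
    n_bands: int = 32
    wavelength_min: float = 400.0
    wavelength_max: float = 1000.0
    fruit_radius_frac: float = 0.35
    informative_bands: tuple[float, ...] = (840.0, 960.0)
    absorption_slope: float = 0.02
    baseline_smoothness: float = 4.0
    illumination_cv: float = 0.05
    noise_sd: float = 0.01
    ssc_mean: float = 11.76
    ssc_sd: float = 1.92
    ssc_min: float = 7.2
    ssc_max: float = 18.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 8:
            raise ValueError("n_bands must be >= 8")
        if not (0.0 < self.fruit_radius_frac < 0.5):
            raise ValueError("fruit_radius_frac must lie in (0, 0.5)")
        if not (self.ssc_min < self.ssc_mean < self.ssc_max):
            raise ValueError("require ssc_min < ssc_mean < ssc_max")
        for wl in self.informative_bands:
            if not (self.wavelength_min <= wl <= self.wavelength_max):
                raise ValueError(
                    f"informative band {wl} nm outside "
                    f"[{self.wavelength_min}, {self.wavelength_max}] nm"
                )

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.n_bands)


@dataclass
class LabeledCube:
    """One simulated acquisition: raw counts plus references and ground truth."""

    raw: np.ndarray
    white_ref: np.ndarray
    black_ref: np.ndarray
    wavelengths: np.ndarray
    ssc: float
    truth_mask: np.ndarray
    sample_id: str = ""


def sample_ssc(params: SyntheticSceneParams, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` SSC values (°Brix): Normal(mean, sd²) rejection-clipped to range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.ssc_sd == 0:
        return np.full(n, params.ssc_mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.ssc_mean, params.ssc_sd, size=2 * (n - filled))
        keep = draw[(draw >= params.ssc_min) & (draw <= params.ssc_max)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _baseline_shape(wl: np.ndarray) -> np.ndarray:
    # apple-like: strong pigment absorption below ~640 nm, bright NIR plateau
    return 0.25 + 0.55 / (1.0 + np.exp(-(wl - 640.0) / 35.0))


def _fruit_reflectance(params: SyntheticSceneParams, ssc: float, rng: np.random.Generator) -> np.ndarray:
    wl = params.wavelengths
    band_step = (params.wavelength_max - params.wavelength_min) / max(params.n_bands - 1, 1)
    bump_sigma = params.baseline_smoothness * band_step
    refl = _baseline_shape(wl).copy()
    amps = np.clip(rng.normal(0.0, _BUMP_AMP_SD, size=len(_BUMP_CENTERS_NM)),
                   -_BUMP_AMP_CLIP, _BUMP_AMP_CLIP)
    for amp, centre in zip(amps, _BUMP_CENTERS_NM):
        refl += amp * np.exp(-0.5 * ((wl - centre) / bump_sigma) ** 2)
    sigma = _ABSORPTION_FWHM_NM / 2.3548200450309493
    depth = params.absorption_slope * (ssc - params.ssc_min)
    for centre in params.informative_bands:
        refl -= depth * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)
    return np.clip(refl, 0.01, 0.99)


def _background_reflectance(params: SyntheticSceneParams) -> np.ndarray:
    wl = params.wavelengths
    t = (wl - params.wavelength_min) / (params.wavelength_max - params.wavelength_min)
    return 0.08 + 0.02 * t


def _lamp_gain(wl: np.ndarray) -> np.ndarray:
    return _GAIN_SCALE * (0.6 + 0.4 * np.exp(-(((wl - 750.0) / 300.0) ** 2)))


def _illumination_field(params: SyntheticSceneParams, rng: np.random.Generator) -> np.ndarray:
    if params.illumination_cv == 0:
        return np.ones((params.n_rows, params.n_cols))
    noise = rng.standard_normal((params.n_rows, params.n_cols))
    smooth = gaussian_filter(noise, sigma=max(params.n_rows, params.n_cols) / 8.0)
    sd = smooth.std()
    if sd > 0:
        smooth = (smooth - smooth.mean()) / sd
    return np.clip(1.0 + params.illumination_cv * smooth, 0.5, None)


def _disk_mask(n_rows: int, n_cols: int, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def generate_cube(params: SyntheticSceneParams, ssc: float, seed: int) -> LabeledCube:
    """Render one labelled acquisition (raw + white/black references) at ``ssc`` °Brix."""
    if not (params.ssc_min <= ssc <= params.ssc_max):
        raise ValueError(f"ssc={ssc} outside [{params.ssc_min}, {params.ssc_max}]")
    rng = np.random.default_rng(seed)
    wl = params.wavelengths
    gain = _lamp_gain(wl)

    mask = _disk_mask(params.n_rows, params.n_cols, params.fruit_radius_frac * min(params.n_rows, params.n_cols))
    scene = np.empty((params.n_rows, params.n_cols, params.n_bands))
    scene[:] = _background_reflectance(params)[None, None, :]
    scene[mask] = _fruit_reflectance(params, ssc, rng)[None, :]

    field = _illumination_field(params, rng)
    raw = scene * field[:, :, None] * gain[None, None, :] + _DARK_COUNTS
    white = np.broadcast_to(_WHITE_REFLECTANCE * gain + _DARK_COUNTS, raw.shape).copy()
    black = np.full(raw.shape, _DARK_COUNTS)
    if params.noise_sd > 0:
        counts_sd = params.noise_sd * gain[None, None, :]
        raw = raw + rng.normal(0.0, 1.0, raw.shape) * counts_sd
        white = white + rng.normal(0.0, 1.0, raw.shape) * (0.3 * counts_sd)
        black = black + rng.normal(0.0, 1.0, raw.shape) * (0.1 * counts_sd)
    return LabeledCube(
        raw=raw,
        white_ref=white,
        black_ref=black,
        wavelengths=wl.copy(),
        ssc=float(ssc),
        truth_mask=mask,
    )


def generate_dataset(
    params: SyntheticSceneParams, n: int, seed: int
) -> tuple[list[LabeledCube], pd.DataFrame]:
    """Generate ``n`` independent labelled cubes plus a matching label table."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    ssc_values = sample_ssc(params, n, rng=rng)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    cubes = []
    for i in range(n):
        cube = generate_cube(params, float(ssc_values[i]), int(child_seeds[i]))
        cube.sample_id = f"s{i:04d}"
        cubes.append(cube)
    labels = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in cubes],
            "ssc_brix": np.round(ssc_values, 6),
            "split": ["unsplit"] * n,
        }
    )
    return cubes, labels


def save_dataset(cubes: list[LabeledCube], labels: pd.DataFrame, outdir: str | Path) -> Path:
    """Write cubes as ENVI pairs (raw/white/black per sample) and labels as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cube in cubes:
        base = outdir / cube.sample_id
        _io.write_envi(base.with_name(base.name + "_raw"), cube.raw, cube.wavelengths)
        _io.write_envi(base.with_name(base.name + "_white"), cube.white_ref, cube.wavelengths)
        _io.write_envi(base.with_name(base.name + "_black"), cube.black_ref, cube.wavelengths)
    _io.write_labels(outdir / "labels.csv", labels)
    return outdir
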