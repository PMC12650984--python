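"""Raw-cube preprocessing: calibration, ROI masking, augmentation, patching.

The stages mirror a standard fruit hyperspectral workflow: white/black
reflectance calibration, band-ratio ROI extraction (715.16 nm / 525.54 nm at a
minimum threshold of 1.6), rotation/mirror augmentation to five images per
acquisition, [0, 1] normalisation, ROI-centred square cropping, and extraction
of pixel-centred patch pairs — one 3x3xB spectral patch and one 31x31xB spatial
patch sharing a centre pixel — which are the networks' input unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic_data import LabeledCube

__all__ = [
    "ReflectanceCube",
    "RoiMask",
    "PatchPair",
    "NoRoiFoundError",
    "calibrate_reflectance",
    "compute_ratio_mask",
    "extract_mean_spectrum",
    "rotate_cube",
    "augment",
    "normalize_cube",
    "crop_to",
    "extract_patch_pairs",
    "FruitPatchDataset",
]

RATIO_BAND_NUM_NM = 715.16
RATIO_BAND_DEN_NM = 525.54
RATIO_THRESHOLD = 1.6
SPECTRAL_PATCH = 3
SPATIAL_PATCH = 31


class NoRoiFoundError(ValueError):
    """Raised when band-ratio thresholding leaves no fruit pixel."""


@dataclass
class ReflectanceCube:
    """Calibrated reflectance raster (rows x cols x bands) with wavelength axis (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError("wavelength axis must match band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class RoiMask:
    mask: np.ndarray
    threshold: float = RATIO_THRESHOLD
    band_num_nm: float = RATIO_BAND_NUM_NM
    band_den_nm: float = RATIO_BAND_DEN_NM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatchPair:
    """Spectral (3x3xB) and spatial (31x31xB) patches sharing a centre pixel."""

    spectral_patch: np.ndarray
    spatial_patch: np.ndarray
    center: tuple[int, int]
    sample_id: str = ""
    label: float = float("nan")


def calibrate_reflectance(
    raw: np.ndarray,
    white: np.ndarray,
    black: np.ndarray,
    wavelengths: np.ndarray | None = None,
) -> ReflectanceCube | np.ndarray:
    """Reflectance calibration ``(raw - black) / (white - black)`` elementwise.

    Pixels where white equals black are set to 0 and reported in a warning.
    Returns a :class:`ReflectanceCube` when ``wavelengths`` is given, else the
    bare array.
    """
    raw = np.asarray(raw, dtype=np.float64)
    white = np.asarray(white, dtype=np.float64)
    black = np.asarray(black, dtype=np.float64)
    if not (raw.shape == white.shape == black.shape):
        raise ValueError(
            f"shape mismatch: raw {raw.shape}, white {white.shape}, black {black.shape}"
        )
    denom = white - black
    bad = denom == 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} pixel-band entries have white == black; set to 0", RuntimeWarning
        )
    out = np.zeros_like(raw)
    np.divide(raw - black, denom, out=out, where=~bad)
    if wavelengths is None:
        return out
    return ReflectanceCube(out, wavelengths)


def calibrate_cube(cube: LabeledCube) -> ReflectanceCube:
    """Calibrate a simulated acquisition into a reflectance cube."""
    return calibrate_reflectance(cube.raw, cube.white_ref, cube.black_ref, cube.wavelengths)


def compute_ratio_mask(
    cube: ReflectanceCube,
    band_num_nm: float = RATIO_BAND_NUM_NM,
    band_den_nm: float = RATIO_BAND_DEN_NM,
    threshold: float = RATIO_THRESHOLD,
) -> RoiMask:
    """Fruit mask from the two-band reflectance ratio at a minimum threshold.

    A pixel is in the ROI iff reflectance(nearest band to ``band_num_nm``) /
    reflectance(nearest band to ``band_den_nm``) >= ``threshold`` (inclusive);
    zero-denominator pixels are excluded.  Only the largest 8-connected
    component is kept, discarding stray background pixels above threshold.
    """
    for wl in (band_num_nm, band_den_nm):
        if not (cube.wavelengths[0] <= wl <= cube.wavelengths[-1]):
            raise ValueError(f"ratio band {wl} nm outside the cube's wavelength range")
    num = cube.data[:, :, cube.band_index(band_num_nm)]
    den = cube.data[:, :, cube.band_index(band_den_nm)]
    valid = den != 0
    ratio = np.zeros_like(num)
    np.divide(num, den, out=ratio, where=valid)
    mask = valid & (ratio >= threshold)
    if not mask.any():
        raise NoRoiFoundError(
            f"no ROI found: no pixel has ratio >= {threshold} at "
            f"{band_num_nm:.2f}/{band_den_nm:.2f} nm"
        )
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return RoiMask(mask, threshold=threshold, band_num_nm=band_num_nm, band_den_nm=band_den_nm)


def extract_mean_spectrum(cube: ReflectanceCube, mask: RoiMask | np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the reflectance over masked pixels."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    return cube.data[m].mean(axis=0)


def _rotate_array(data: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    if order == 0:
        return ndimage.rotate(data, angle_deg, axes=(1, 0), reshape=False, order=0, mode="constant", cval=0)
    # bilinear, fill = per-band median (background level) via a shift trick
    med = np.median(data, axis=(0, 1), keepdims=True)
    rot = ndimage.rotate(data - med, angle_deg, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0)
    return rot + med


def rotate_cube(cube: ReflectanceCube, angle_deg: float) -> ReflectanceCube:
    """Rotate about the image centre (bilinear per band, background-median fill)."""
    return ReflectanceCube(_rotate_array(cube.data, angle_deg, order=1), cube.wavelengths)


def _augment_angles(seed: int) -> tuple[float, float, float]:
    rng = np.random.default_rng(seed)
    return (
        float(rng.uniform(0.0, 30.0)),
        float(rng.uniform(150.0, 180.0)),
        float(rng.uniform(180.0, 210.0)),
    )


def _pad_square(data: np.ndarray) -> np.ndarray:
    h, w = data.shape[:2]
    if h == w:
        return data
    size = max(h, w)
    pad = [(0, size - h), (0, size - w)] + [(0, 0)] * (data.ndim - 2)
    return np.pad(data, pad, mode="reflect")


def augment(cube: ReflectanceCube, seed: int) -> list[ReflectanceCube]:
    """Five-image augmentation: original, three random rotations, one mirror.

    Rotation angles are drawn uniformly from [0°, 30°], [150°, 180°] and
    [180°, 210°] under ``seed``; the fifth image is the left-right mirror of
    the original.  Non-square cubes are reflect-padded to square first, and all
    five outputs share that shape.
    """
    data = _pad_square(cube.data)
    base = ReflectanceCube(data, cube.wavelengths)
    out = [base]
    for angle in _augment_angles(seed):
        out.append(ReflectanceCube(_rotate_array(data, angle, order=1), cube.wavelengths))
    out.append(ReflectanceCube(data[:, ::-1, :].copy(), cube.wavelengths))
    return out


def normalize_cube(cube: ReflectanceCube) -> ReflectanceCube:
    """Min-max scale the whole cube to [0, 1]; a constant cube maps to zeros."""
    if not np.all(np.isfinite(cube.data)):
        raise ValueError("cube contains non-finite values")
    lo, hi = cube.data.min(), cube.data.max()
    if hi == lo:
        warnings.warn("constant cube: normalisation maps it to all zeros", RuntimeWarning)
        return ReflectanceCube(np.zeros_like(cube.data), cube.wavelengths)
    return ReflectanceCube((cube.data - lo) / (hi - lo), cube.wavelengths)


def crop_to(
    cube: ReflectanceCube, mask: RoiMask, size: int = 224
) -> tuple[ReflectanceCube, RoiMask]:
    """Square crop of side ``size`` centred on the ROI centroid.

    The window is clamped to the image; if the image is smaller than ``size``
    it is reflect-padded (mask padded with False) before cropping.
    """
    if size < SPATIAL_PATCH:
        raise ValueError(f"crop size must be >= {SPATIAL_PATCH}")
    data, m = cube.data, mask.mask
    h, w = data.shape[:2]
    if h < size or w < size:
        ph, pw = max(0, size - h), max(0, size - w)
        pad2 = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
        data = np.pad(data, pad2 + [(0, 0)], mode="reflect")
        m = np.pad(m, pad2, mode="constant", constant_values=False)
        h, w = data.shape[:2]
    rows, cols = np.nonzero(m)
    cy, cx = rows.mean(), cols.mean()
    r0 = int(np.clip(round(cy) - size // 2, 0, h - size))
    c0 = int(np.clip(round(cx) - size // 2, 0, w - size))
    sub = data[r0 : r0 + size, c0 : c0 + size]
    subm = m[r0 : r0 + size, c0 : c0 + size]
    return (
        ReflectanceCube(sub.copy(), cube.wavelengths),
        RoiMask(subm.copy(), mask.threshold, mask.band_num_nm, mask.band_den_nm),
    )


def extract_patch_pairs(
    cube: ReflectanceCube,
    mask: RoiMask | np.ndarray,
    k_centers: int,
    seed: int,
    sample_id: str = "",
    label: float = float("nan"),
    spectral_size: int = SPECTRAL_PATCH,
    spatial_size: int = SPATIAL_PATCH,
) -> list[PatchPair]:
    """Sample ``k_centers`` ROI pixels and cut a (3x3, 31x31) patch pair at each.

    Centres are drawn uniformly without replacement (all ROI pixels if fewer
    are available); patches reaching past the image border are reflect-padded.
    """
    if k_centers < 1:
        raise ValueError("k_centers must be >= 1")
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(m)
    rng = np.random.default_rng(seed)
    k = min(k_centers, rows.size)
    idx = rng.choice(rows.size, size=k, replace=False)
    pad = spatial_size // 2
    padded = np.pad(cube.data, [(pad, pad), (pad, pad), (0, 0)], mode="reflect")
    half_sp = spectral_size // 2
    pairs = []
    for i in idx:
        r, c = int(rows[i]), int(cols[i])
        pr, pc = r + pad, c + pad
        spec = padded[pr - half_sp : pr + half_sp + 1, pc - half_sp : pc + half_sp + 1]
        spat = padded[pr - pad : pr + pad + 1, pc - pad : pc + pad + 1]
        pairs.append(
            PatchPair(
                spectral_patch=spec.copy(),
                spatial_patch=spat.copy(),
                center=(r, c),
                sample_id=sample_id,
                label=label,
            )
        )
    return pairs


@dataclass
class FruitPatchDataset:
    """Per-fruit calibrated cubes + masks + labels, with on-demand patch extraction.

    Augmentation (five images per fruit) is applied only when requested, so
    cross-validation can augment training folds while leaving validation folds
    untouched; patches inherit the fruit's sample id either way.
    """

    sample_ids: list[str]
    cubes: list[ReflectanceCube]
    masks: list[np.ndarray]
    labels: np.ndarray
    k_centers: int = 8

    @classmethod
    def from_labeled_cubes(
        cls,
        cubes,
        threshold: float = RATIO_THRESHOLD,
        k_centers: int = 8,
        crop_size: int | None = None,
        dtype=np.float32,
    ) -> "FruitPatchDataset":
        """Calibrate, mask and normalise an iterable of labelled cubes.

        Cubes are consumed one at a time (a generator works and keeps peak
        memory at one raw cube); the stored reflectance is float32 by default.
        """
        ids, refl, masks, labels = [], [], [], []
        for lc in cubes:
            cal = calibrate_cube(lc)
            mask = compute_ratio_mask(cal, threshold=threshold)
            cal = normalize_cube(cal)
            if crop_size is not None:
                cal, mask = crop_to(cal, mask, size=crop_size)
            ids.append(lc.sample_id)
            refl.append(ReflectanceCube(cal.data.astype(dtype), cal.wavelengths))
            masks.append(mask.mask)
            labels.append(lc.ssc)
        return cls(ids, refl, masks, np.asarray(labels, dtype=float), k_centers=k_centers)

    @classmethod
    def from_params(
        cls,
        params,
        n: int,
        seed: int,
        threshold: float = RATIO_THRESHOLD,
        k_centers: int = 8,
        crop_size: int | None = None,
        dtype=np.float32,
    ) -> tuple["FruitPatchDataset", "pd.DataFrame"]:
        """Generate a synthetic dataset and preprocess it cube by cube.

        Raw/white/black count cubes are discarded as soon as each sample is
        calibrated, so peak memory stays near a single acquisition.
        """
        import pandas as pd

        from .synthetic_data import generate_cube, sample_ssc

        if n < 2:
            raise ValueError("n must be >= 2")
        rng = np.random.default_rng(seed)
        ssc_values = sample_ssc(params, n, rng=rng)
        child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)

        def _cubes():
            for i in range(n):
                cube = generate_cube(params, float(ssc_values[i]), int(child_seeds[i]))
                cube.sample_id = f"s{i:04d}"
                yield cube

        ds = cls.from_labeled_cubes(
            _cubes(), threshold=threshold, k_centers=k_centers,
            crop_size=crop_size, dtype=dtype,
        )
        labels = pd.DataFrame(
            {"sample_id": ds.sample_ids, "ssc_brix": np.round(ssc_values, 6),
             "split": ["unsplit"] * n}
        )
        return ds, labels

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset_indices(self, ids: list[str]) -> list[int]:
        lookup = {sid: i for i, sid in enumerate(self.sample_ids)}
        return [lookup[s] for s in ids]

    def patch_arrays(
        self, ids: list[str], seed: int, augment_data: bool = False,
        k_centers: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Stack patch pairs for the given fruit ids.

        Returns (Xspec (N,3,3,B), Xspat (N,31,31,B), y °Brix (N,), patch sample ids).
        With ``augment_data`` each fruit contributes patches from all five
        augmented images (masks rotated nearest-neighbour alongside).
        """
        k = k_centers if k_centers is not None else self.k_centers
        xs, xp, ys, pids = [], [], [], []
        seq = np.random.SeedSequence(seed).generate_state(len(ids) * 8) % (2**31)
        si = 0
        for sid in ids:
            i = self.subset_indices([sid])[0]
            cube, mask, label = self.cubes[i], self.masks[i], self.labels[i]
            views: list[tuple[ReflectanceCube, np.ndarray]] = [(cube, mask)]
            if augment_data:
                aug_seed = int(seq[si]); si += 1
                aug = augment(cube, aug_seed)
                angles = _augment_angles(aug_seed)
                mask_sq = _pad_square(mask[..., None])[..., 0]
                rot_masks = [
                    _rotate_array(mask_sq.astype(float), a, order=0) > 0.5 for a in angles
                ]
                views = [
                    (aug[0], mask_sq),
                    *zip(aug[1:4], rot_masks),
                    (aug[4], mask_sq[:, ::-1]),
                ]
            for view_cube, view_mask in views:
                pseed = int(seq[si]); si += 1
                pairs = extract_patch_pairs(
                    view_cube, view_mask, k, pseed, sample_id=sid, label=label
                )
                for p in pairs:
                    xs.append(p.spectral_patch)
                    xp.append(p.spatial_patch)
                    ys.append(p.label)
                    pids.append(sid)
        return np.stack(xs), np.stack(xp), np.asarray(ys), pids
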