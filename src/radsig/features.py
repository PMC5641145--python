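"""Per-modality radiomic feature extraction.

A modality yields exactly 485 features: 17 first-order statistics and 36
texture features on the original image, 8 mask-only shape features, and the
same 17 + 36 metrics on each of the 8 subbands of a one-level 3D wavelet
decomposition (424 wavelet features).  Two modalities give a 970-entry
patient vector.

Conventions: variance / sd / skewness / kurtosis use population (n)
normalization and kurtosis is non-excess; intensity entropy and uniformity
use the same fixed equal-width binning as the texture features; the wavelet
transform is the decimated separable DWT with the coif1 filter (periodic
boundary handling), subbands mapped back to the original grid by
nearest-neighbor upsampling before mask restriction.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .io import TumorMask, VolumeImage
from .names import (
    MODALITIES,
    N_FEATURES_PER_MODALITY,
    N_FEATURES_PER_PATIENT,
    FeatureName,
    modality_features,
)
from .texture import DIRECTIONS_13, discretize, texture_features

DEFAULT_N_BINS = 32
DEFAULT_WAVELET = "coif1"

#: subband index 1..8 -> pywt dwtn key ({L,H}^3 lexicographic, L='a', H='d')
_SUBBAND_KEYS = {
    1: "aaa",
    2: "aad",
    3: "ada",
    4: "add",
    5: "daa",
    6: "dad",
    7: "dda",
    8: "ddd",
}


def first_order_features(volume, mask, n_bins: int = DEFAULT_N_BINS) -> dict[str, float]:
    """The 17 first-order statistics of the in-mask intensity distribution.

    Entropy and uniformity are computed on an ``n_bins`` equal-width
    histogram of the in-mask values.  Robust MAD (``rmad``) is the mean
    absolute deviation of the values inside the [p10, p90] range.
    """
    x = _masked_values(volume, mask)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = float(np.sqrt(var))
    m2 = var
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # non-excess
    else:
        skew = 0.0
        kurt = 0.0
    p10 = float(np.percentile(x, 10))
    p90 = float(np.percentile(x, 90))
    inner = x[(x >= p10) & (x <= p90)]
    if x.min() == x.max():
        entropy, uniformity = 0.0, 1.0
    else:
        counts, _ = np.histogram(x, bins=n_bins, range=(float(x.min()), float(x.max())))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log(p)).sum())
        uniformity = float((p**2).sum())
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
        "rms": float(np.sqrt((x**2).mean())),
        "mad": float(np.abs(x - mean).mean()),
        "rmad": float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0,
        "p10": p10,
        "p90": p90,
    }


def voxel_surface_area(mask: TumorMask) -> float:
    """Surface area by counting exposed voxel faces (mm^2).

    Kept as a simple cross-check for box-like masks; the shape features use
    the smoother triangulated-isosurface estimate.
    """
    m = mask.voxels
    sx, sy, sz = mask.spacing
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    padded = np.pad(m, 1)
    area = 0.0
    for ax in range(3):
        d = np.diff(padded.astype(np.int8), axis=ax)
        area += np.abs(d).sum() * face[ax]
    return float(area)


def max_3d_diameter(mask: TumorMask) -> float:
    """Greatest pairwise physical distance between foreground voxel centers (mm)."""
    coords = np.argwhere(mask.voxels) * np.asarray(mask.spacing)
    if coords.shape[0] < 2:
        return 0.0
    if coords.shape[0] > 400:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass  # degenerate geometry (coplanar etc.) — brute force below
    return float(pdist(coords).max())


def shape_features(mask: TumorMask) -> dict[str, float]:
    """The 8 shape/size features, all in physical (mm) units.

    Surface area comes from a triangulated isosurface of the binary mask at
    iso-level 0.5 (mask padded by one background voxel so the surface is
    closed).
    """
    n = mask.n_voxels
    spacing = np.asarray(mask.spacing)
    volume = float(n * spacing.prod())
    padded = np.pad(mask.voxels.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(mesh_surface_area(verts, faces))
    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "volume": volume,
        "surface_area": area,
        "surface_to_volume": area / volume,
        "sphericity": float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area),
        "compactness1": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "compactness2": float(36.0 * np.pi * volume**2 / area**3),
        "spherical_disproportion": float(area / (4.0 * np.pi * r_equiv**2)),
        "Max3D": max_3d_diameter(mask),
    }


def wavelet_subbands(volume, mask, wavelet: str = DEFAULT_WAVELET) -> dict[int, np.ndarray]:
    """One-level 3D wavelet decomposition of the mask's bounding box.

    Returns 8 full-grid volumes indexed 1..8 = LLL..HHH.  Each decimated
    subband is mapped back onto the original grid by nearest-neighbor (x2)
    upsampling and cropping to the bounding box, with zeros outside, so that
    features can be computed under the original mask.
    """
    intens = volume.intensities if isinstance(volume, VolumeImage) else np.asarray(volume)
    m = mask.voxels if isinstance(mask, TumorMask) else np.asarray(mask).astype(bool)
    w = pywt.Wavelet(wavelet)
    nz = np.argwhere(m)
    lo = nz.min(axis=0)
    hi = nz.max(axis=0) + 1
    bbox_shape = tuple(hi - lo)
    if min(bbox_shape) < w.dec_len:
        raise ValueError(
            f"mask bounding box {bbox_shape} is smaller than the {wavelet} filter "
            f"support; each axis must span at least {w.dec_len} voxels"
        )
    region = intens[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(np.float64)
    coeffs = pywt.dwtn(region, w, mode="periodization")
    out: dict[int, np.ndarray] = {}
    for idx, key in _SUBBAND_KEYS.items():
        sub = coeffs[key]
        up = sub
        for ax in range(3):
            up = np.repeat(up, 2, axis=ax)
        up = up[: bbox_shape[0], : bbox_shape[1], : bbox_shape[2]]
        full = np.zeros(intens.shape, dtype=np.float64)
        full[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = up
        out[idx] = full
    return out


def _masked_values(volume, mask) -> np.ndarray:
    intens = volume.intensities if isinstance(volume, VolumeImage) else np.asarray(volume)
    m = mask.voxels if isinstance(mask, TumorMask) else np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty region of interest")
    return intens[m].astype(np.float64)


def extract_modality(
    volume: VolumeImage,
    mask: TumorMask,
    n_bins: int = DEFAULT_N_BINS,
    wavelet: str = DEFAULT_WAVELET,
    directions=DIRECTIONS_13,
) -> dict[str, float]:
    """The full 485-entry feature vector of one modality, canonically ordered."""
    if volume.intensities.shape != mask.voxels.shape:
        raise ValueError("volume and mask grids are not aligned")
    values: dict[tuple[str, int, str], float] = {}

    def put(family: str, subband: int, feats: dict[str, float]) -> None:
        for metric, v in feats.items():
            values[(family, subband, metric)] = v

    put("fos", 0, first_order_features(volume, mask, n_bins))
    put("shape", 0, shape_features(mask))
    tex0 = texture_features(discretize(volume, mask, n_bins), directions)
    put("GLCM", 0, {k[5:]: v for k, v in tex0.items() if k.startswith("GLCM_")})
    put("GLRLM", 0, {k[6:]: v for k, v in tex0.items() if k.startswith("GLRLM_")})
    for idx, sub in wavelet_subbands(volume, mask, wavelet).items():
        put("fos", idx, first_order_features(sub, mask, n_bins))
        tex = texture_features(discretize(sub, mask, n_bins), directions)
        put("GLCM", idx, {k[5:]: v for k, v in tex.items() if k.startswith("GLCM_")})
        put("GLRLM", idx, {k[6:]: v for k, v in tex.items() if k.startswith("GLRLM_")})

    out: dict[str, float] = {}
    for f in modality_features(volume.modality):
        out[f.render()] = values[(f.family, f.subband, f.metric)]
    assert len(out) == N_FEATURES_PER_MODALITY
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features: {bad[:5]}")
    return out


def extract_patient(
    cet1: tuple[VolumeImage, TumorMask],
    t2: tuple[VolumeImage, TumorMask],
    n_bins: int = DEFAULT_N_BINS,
    wavelet: str = DEFAULT_WAVELET,
) -> dict[str, float]:
    """Concatenated 970-entry vector for a two-modality patient."""
    pairs = {"CET1-w": cet1, "T2-w": t2}
    for mod, pair in pairs.items():
        if pair is None:
            raise ValueError(f"missing modality {mod}: no partial extraction")
        vol, _ = pair
        if vol.modality != mod:
            raise ValueError(f"expected modality {mod}, got {vol.modality!r}")
    out: dict[str, float] = {}
    for mod in MODALITIES:
        vol, msk = pairs[mod]
        out.update(extract_modality(vol, msk, n_bins, wavelet))
    assert len(out) == N_FEATURES_PER_PATIENT
    return out


def family_counts(features: dict[str, float]) -> dict[str, int]:
    """Count features by the four-family taxonomy (per the full vector given)."""
    counts = {"fos-original": 0, "shape": 0, "texture-original": 0, "wavelet": 0}
    for name in features:
        fam, sub = _classify(name)
        counts[fam if sub == 0 else "wavelet"] += 1
    return counts


def _classify(name: str) -> tuple[str, int]:
    parts = name.split("_")
    if len(parts) < 3 or not parts[1].isdigit():  # e.g. "T2-w_Max3D", "T2-w_surface_area"
        return "shape", 0
    sub = int(parts[1])
    fam = parts[2]
    if fam == "fos":
        return "fos-original", sub
    return "texture-original", sub
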