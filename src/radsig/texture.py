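"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture analysis.

Intensities inside the region of interest are first discretized into a fixed
number of equal-width gray levels; co-occurrence and run-length matrices are
then built over the 13 unique 3D directions (26-connectivity modulo sign) at
distance 1 voxel.  The GLCM is accumulated symmetrically over all directions
into a single probability matrix; the GLRLM is computed per direction and its
features averaged over directions.

All logarithms are natural; 0·log 0 is taken as 0.  Degenerate regions
(a single occupied gray level) use fixed conventions — correlation = 1,
MCC = 1, IMC1 = 0, entropies = 0 — so every feature is finite on any valid
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the 13 unique direction vectors of 26-connectivity modulo sign
#: (first nonzero component positive).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


def _as_array(volume) -> np.ndarray:
    """Accept a VolumeImage/TumorMask or a bare ndarray."""
    for attr in ("intensities", "voxels"):
        if hasattr(volume, attr):
            return np.asarray(getattr(volume, attr))
    return np.asarray(volume)


@dataclass
class DiscretizedVolume:
    """Gray-level volume: in-mask voxels carry a level in 1..ng, 0 outside."""

    levels: np.ndarray  # int grid, 0 = outside mask
    ng: int
    bin_edges: np.ndarray  # length ng + 1, strictly increasing
    mask: np.ndarray  # boolean grid
    degenerate: bool = False  # constant in-mask intensity


def discretize(volume, mask, n_bins: int = 32) -> DiscretizedVolume:
    """Equal-width binning of in-mask intensities into ``n_bins`` gray levels.

    Bins are half-open ``[e_k, e_{k+1})`` with the final bin closed, so the
    in-mask maximum maps to level ``n_bins`` (never ``n_bins + 1``).  A
    constant region maps every voxel to level 1 and sets ``degenerate``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    intensities = _as_array(volume).astype(float)
    m = _as_array(mask).astype(bool)
    if not m.any():
        raise ValueError("empty region of interest")
    vals = intensities[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(intensities.shape, dtype=np.int32)
    if lo == hi:
        edges = lo + np.arange(n_bins + 1, dtype=float)  # arbitrary unit-width edges
        levels[m] = 1
        return DiscretizedVolume(levels, n_bins, edges, m, degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    lv = np.digitize(vals, edges[1:-1], right=False) + 1  # 1..n_bins, max inclusive
    levels[m] = lv
    return DiscretizedVolume(levels, n_bins, edges, m, degenerate=False)


@dataclass
class GLCMatrix:
    probabilities: np.ndarray  # ng x ng, symmetric, sums to 1
    direction_set: tuple[tuple[int, int, int], ...]
    distance: int


@dataclass
class GLRLMatrix:
    counts: np.ndarray  # ng x max_run_length run counts
    direction: tuple[int, int, int]
    n_runs: int
    n_voxels: int  # in-mask voxels (each belongs to exactly one run)


def _shifted_slices(shape, offset):
    """Slice pair (a, b) such that arr[b] = arr[a] shifted by ``offset``."""
    a, b = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            a.append(slice(0, n - o))
            b.append(slice(o, n))
        else:
            a.append(slice(-o, n))
            b.append(slice(0, n + o))
    return tuple(a), tuple(b)


def glcm(disc: DiscretizedVolume, directions=DIRECTIONS_13, distance: int = 1) -> GLCMatrix:
    """Symmetric co-occurrence probability matrix accumulated over directions."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    directions = tuple(tuple(int(c) for c in d) for d in directions)
    if any(d == (0, 0, 0) for d in directions):
        raise ValueError("direction offsets must be nonzero")
    ng = disc.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    lv, m = disc.levels, disc.mask
    for d in directions:
        off = tuple(distance * c for c in d)
        if any(abs(o) >= n for o, n in zip(off, lv.shape)):
            continue
        sa, sb = _shifted_slices(lv.shape, off)
        valid = m[sa] & m[sb]
        if not valid.any():
            continue
        i = lv[sa][valid] - 1
        j = lv[sb][valid] - 1
        np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T  # count each pair in both orders
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurrences: mask has no valid voxel pair in any direction")
    return GLCMatrix(counts / total, directions, distance)


def glrlm(disc: DiscretizedVolume, direction) -> GLRLMatrix:
    """Run-length matrix along one direction.

    A run is a maximal set of collinear, consecutive in-mask voxels sharing a
    gray level; out-of-mask voxels break runs.  Every in-mask voxel belongs
    to exactly one run, so sum(count * length) equals the in-mask voxel count.
    """
    d = np.asarray(direction, dtype=np.int64)
    if not d.any():
        raise ValueError("direction must be a nonzero integer triple")
    m = disc.mask
    idx = np.argwhere(m)  # (n, 3)
    n_vox = idx.shape[0]
    lv = disc.levels[m.astype(bool)]  # same order as argwhere (C order)
    # line identity: cross(v, d) is constant along a line with direction d;
    # position along the line: dot(v, d), stepping by |d|^2 between neighbors.
    cross = np.cross(idx, d)
    t = idx @ d
    order = np.lexsort((t, cross[:, 2], cross[:, 1], cross[:, 0]))
    cs, ts, ls = cross[order], t[order], lv[order]
    step = int(d @ d)
    same_line = np.all(cs[1:] == cs[:-1], axis=1)
    contiguous = (ts[1:] - ts[:-1]) == step
    same_level = ls[1:] == ls[:-1]
    new_run = np.ones(n_vox, dtype=bool)
    new_run[1:] = ~(same_line & contiguous & same_level)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, n_vox))
    run_levels = ls[starts]
    max_len = int(lengths.max())
    counts = np.zeros((disc.ng, max_len), dtype=np.float64)
    np.add.at(counts, (run_levels - 1, lengths - 1), 1.0)
    n_runs = len(starts)
    return GLRLMatrix(counts, tuple(int(c) for c in d), n_runs, n_vox)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 25 co-occurrence features (Haralick set plus common extensions)."""
    p = m.probabilities
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_sum, (ii + jj - 2).astype(int), p)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)

    diff = ii - jj
    adiff = np.abs(diff)

    out: dict[str, float] = {}
    out["energy"] = float((p**2).sum())
    out["contrast"] = float((diff**2 * p).sum())
    if sd_x * sd_y > 0:
        out["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        out["correlation"] = 1.0  # constant region
    out["variance"] = float((((ii - mu_x) ** 2) * p).sum())
    out["IDM"] = float((p / (1.0 + diff**2)).sum())
    sum_avg = float((ksum * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)
    hxy = _entropy(p)
    out["entropy"] = hxy
    diff_avg = float((kdiff * p_diff).sum())
    out["difference_average"] = diff_avg
    out["difference_variance"] = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)

    hx, hy = _entropy(px), _entropy(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log(pxy[nz2])).sum())
    out["IMC1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["IMC2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["autocorrelation"] = float((ii * jj * p).sum())
    centered = ii + jj - mu_x - mu_y
    out["cluster_shade"] = float((centered**3 * p).sum())
    out["cluster_prominence"] = float((centered**4 * p).sum())
    out["cluster_tendency"] = float((centered**2 * p).sum())
    out["dissimilarity"] = float((adiff * p).sum())
    out["ID"] = float((p / (1.0 + adiff)).sum())
    out["IDN"] = float((p / (1.0 + adiff / ng)).sum())
    out["IDMN"] = float((p / (1.0 + diff**2 / ng**2)).sum())
    out["max_probability"] = float(p.max())
    off = adiff > 0
    out["inverse_variance"] = float((p[off] / diff[off] ** 2).sum())
    out["MCC"] = _mcc(p, px, py)
    return out


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second eigenvalue of Q."""
    active = px > 0
    if active.sum() < 2:
        return 1.0  # single occupied level
    pa = p[np.ix_(active, active)]
    pxa, pya = px[active], py[active]
    a = pa / pxa[:, None]
    b = pa / pya[None, :]
    q = a @ b.T
    ev = np.sort(np.real(np.linalg.eigvals(q)))
    return float(np.clip(np.sqrt(max(ev[-2], 0.0)), 0.0, 1.0))


def glrlm_features(m: GLRLMatrix) -> dict[str, float]:
    """The 11 run-length features."""
    r = m.counts
    nr = float(m.n_runs)
    if nr < 1:
        raise ValueError("run-length matrix has no runs")
    ng, max_len = r.shape
    i2 = np.arange(1, ng + 1, dtype=float) ** 2  # gray level squared
    j2 = np.arange(1, max_len + 1, dtype=float) ** 2  # run length squared
    out = {
        "SRE": float((r / j2[None, :]).sum() / nr),
        "LRE": float((r * j2[None, :]).sum() / nr),
        "GLN": float((r.sum(axis=1) ** 2).sum() / nr),
        "RLN": float((r.sum(axis=0) ** 2).sum() / nr),
        "RP": nr / float(m.n_voxels),
        "LGLRE": float((r / i2[:, None]).sum() / nr),
        "HGLRE": float((r * i2[:, None]).sum() / nr),
        "SRLGLE": float((r / (i2[:, None] * j2[None, :])).sum() / nr),
        "SRHGLE": float((r * i2[:, None] / j2[None, :]).sum() / nr),
        "LRLGLE": float((r * j2[None, :] / i2[:, None]).sum() / nr),
        "LRHGLE": float((r * i2[:, None] * j2[None, :]).sum() / nr),
    }
    return out


def texture_features(
    disc: DiscretizedVolume,
    directions=DIRECTIONS_13,
    distance: int = 1,
) -> dict[str, float]:
    """All 36 texture features of one discretized volume.

    GLCM features come from the single direction-aggregated matrix; GLRLM
    features are averaged over the per-direction matrices.  Keys are prefixed
    ``GLCM_`` / ``GLRLM_``.
    """
    out = {f"GLCM_{k}": v for k, v in glcm_features(glcm(disc, directions, distance)).items()}
    acc: dict[str, float] = {}
    for d in directions:
        for k, v in glrlm_features(glrlm(disc, d)).items():
            acc[k] = acc.get(k, 0.0) + v
    n = len(tuple(directions))
    for k, v in acc.items():
        out[f"GLRLM_{k}"] = v / n
    return out
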