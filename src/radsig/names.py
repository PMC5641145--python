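"""Canonical radiomic feature names.

Each MRI sequence (modality) yields exactly 485 features:

* 17 first-order statistics (``fos``) on the original image,
* 8 shape/size features computed from the mask alone,
* 36 texture features (25 GLCM + 11 GLRLM) on the original image,
* 424 wavelet features: the same 17 fos + 36 texture metrics on each of the
  8 subbands of a one-level 3D wavelet decomposition.

Rendered names follow the ``<modality>_<subband>_<family>_<metric>`` token
style (e.g. ``CET1-w_5_fos_median``); subband 0 is the original image and
1..8 index the LLL..HHH subbands.  Shape features depend only on the mask
and carry no subband token (e.g. ``T2-w_Max3D``).
"""

from __future__ import annotations

from dataclasses import dataclass

MODALITIES = ("CET1-w", "T2-w")

#: subband 0 is the unfiltered image; 1..8 are the {L,H}^3 wavelet subbands
#: in lexicographic order with L < H per axis.
SUBBAND_LABELS = {
    0: "original",
    1: "LLL",
    2: "LLH",
    3: "LHL",
    4: "LHH",
    5: "HLL",
    6: "HLH",
    7: "HHL",
    8: "HHH",
}

FOS_METRICS = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "sd",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "rms",
    "mad",
    "rmad",
    "p10",
    "p90",
)

SHAPE_METRICS = (
    "volume",
    "surface_area",
    "surface_to_volume",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "Max3D",
)

GLCM_METRICS = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "IDM",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "IMC1",
    "IMC2",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "cluster_tendency",
    "dissimilarity",
    "ID",
    "IDN",
    "IDMN",
    "max_probability",
    "inverse_variance",
    "MCC",
)

GLRLM_METRICS = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGLRE",
    "HGLRE",
    "SRLGLE",
    "SRHGLE",
    "LRLGLE",
    "LRHGLE",
)

_FAMILY_ORDER = {"fos": 0, "shape": 1, "GLCM": 2, "GLRLM": 3}
_FAMILY_METRICS = {
    "fos": FOS_METRICS,
    "shape": SHAPE_METRICS,
    "GLCM": GLCM_METRICS,
    "GLRLM": GLRLM_METRICS,
}

N_FEATURES_PER_MODALITY = 485
N_FEATURES_PER_PATIENT = 970


@dataclass(frozen=True)
class FeatureName:
    """One canonical feature identifier.

    ``subband`` is 0 for the original image; shape features ignore it.
    """

    modality: str
    family: str  # 'fos' | 'shape' | 'GLCM' | 'GLRLM'
    metric: str
    subband: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.family not in _FAMILY_METRICS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.metric not in _FAMILY_METRICS[self.family]:
            raise ValueError(f"unknown {self.family} metric {self.metric!r}")
        if self.family == "shape" and self.subband != 0:
            raise ValueError("shape features carry no subband index")
        if not 0 <= self.subband <= 8:
            raise ValueError(f"subband must be in 0..8, got {self.subband}")

    def render(self) -> str:
        if self.family == "shape":
            return f"{self.modality}_{self.metric}"
        return f"{self.modality}_{self.subband}_{self.family}_{self.metric}"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (
            _FAMILY_ORDER[self.family],
            self.subband,
            _FAMILY_METRICS[self.family].index(self.metric),
        )


def modality_features(modality: str) -> list[FeatureName]:
    """All 485 features of one modality in canonical (family, subband, metric) order."""
    out: list[FeatureName] = []
    for sub in range(9):
        for m in FOS_METRICS:
            out.append(FeatureName(modality, "fos", m, sub))
    for m in SHAPE_METRICS:
        out.append(FeatureName(modality, "shape", m))
    for family in ("GLCM", "GLRLM"):
        for sub in range(9):
            for m in _FAMILY_METRICS[family]:
                out.append(FeatureName(modality, family, m, sub))
    out.sort(key=lambda f: f.sort_key)
    assert len(out) == N_FEATURES_PER_MODALITY
    return out


def patient_features() -> list[FeatureName]:
    """All 970 features of a two-modality patient, CET1-w block then T2-w."""
    return [f for mod in MODALITIES for f in modality_features(mod)]


def canonical_names(modality: str | None = None) -> list[str]:
    """Rendered canonical feature names (485 for one modality, 970 for both)."""
    feats = modality_features(modality) if modality else patient_features()
    return [f.render() for f in feats]


_CANONICAL_RANK = {name: i for i, name in enumerate(canonical_names())}


def canonical_rank(name: str) -> int:
    """Position of a rendered feature name in the canonical patient order."""
    try:
        return _CANONICAL_RANK[name]
    except KeyError:
        raise KeyError(f"not a canonical feature name: {name!r}") from None


def feature_dictionary() -> list[dict]:
    """Machine-readable listing of all canonical features (for JSON export)."""
    return [
        {
            "name": f.render(),
            "modality": f.modality,
            "family": f.family,
            "metric": f.metric,
            "subband": f.subband,
            "subband_label": "" if f.family == "shape" else SUBBAND_LABELS[f.subband],
        }
        for f in patient_features()
    ]
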