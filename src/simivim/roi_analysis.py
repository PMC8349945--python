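"""ROI-level analysis: means, percent-red, masks and malignancy calls.

Mirrors the reading workflow of the study: one two-dimensional region of
interest (ROI) per lesion on a representative slice, restricted to the
vital (b-800 hyperintense) tissue, with necrotic/cystic/scar voxels
(hyperintense on b-0 and/or hypointense on b-800) excluded. ROI means of
the parameter maps feed the cutoff rules; ROI means of the index maps
are the percent-red scores (mean of a 0/100 map = 100 x red fraction).
The human four-point visual judgment is replaced by a quantitative
red-voxel-dominance surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index_maps import CutoffSet, IndexMap, RED_VALUE
from .ivim_maps import ParameterMap
from .phantom import BENIGN_CLASSES, MALIGNANT_CLASSES, PhantomScene

__all__ = [
    "ROIMask",
    "LesionRecord",
    "VisualSurrogate",
    "EmptyROIError",
    "INDEX_PCT_CUTOFFS",
    "roi_mean",
    "hyperintensity_mask",
    "exclusion_mask",
    "classify_lesion_quantitative",
    "visual_surrogate",
    "truth_for_class",
    "roi_from_lesion",
]

#: Published percent-red cutoffs of the index maps for the malignant-vs-
#: benign contrast (test direction "<": a higher percentage is a more
#: positive, i.e. more malignant, result).
INDEX_PCT_CUTOFFS = {"I_Df": 50.2, "I_ADC": 53.4, "I_D": 51.0, "I_f": 57.0}

RATINGS = ("definitely_malignant", "probably_malignant",
           "probably_benign", "definitely_benign")


class EmptyROIError(ValueError):
    """The analysed voxel set of a ROI is empty."""


@dataclass
class ROIMask:
    """Voxel set of one lesion ROI with an optional exclusion subset.

    ``mask`` and ``exclusion`` are boolean volumes on the image grid; the
    analysed set is ``mask & ~exclusion``. ``slice_index`` records the
    representative slice for a single-slice ROI (None for multi-slice
    ROIs, which are accepted but depart from the single-slice reading
    protocol).
    """

    lesion_id: int
    mask: np.ndarray
    slice_index: int | None = None
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.exclusion is None:
            self.exclusion = np.zeros_like(self.mask)
        else:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != self.mask.shape:
                raise ValueError("exclusion must share the ROI grid")
            if np.any(self.exclusion & ~self.mask):
                raise ValueError("exclusion must be a subset of the ROI voxel set")
        if not self.analysed().any():
            raise EmptyROIError(f"lesion {self.lesion_id}: analysed ROI is empty")

    def analysed(self) -> np.ndarray:
        return self.mask & ~self.exclusion

    def with_exclusion(self, exclusion: np.ndarray) -> "ROIMask":
        return ROIMask(self.lesion_id, self.mask, self.slice_index,
                       exclusion & self.mask)


@dataclass
class LesionRecord:
    """Per-lesion ROI summary: class, truth and ROI means of every map.

    ``means`` keys: Dprime/fprime/ADC in internal units (mm^2/s,
    fraction) and I_D/I_f/I_ADC/I_Df as percentages in [0, 100].
    """

    lesion_id: int
    class_label: str
    truth: str  # {"malignant", "benign"}
    means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth not in ("malignant", "benign"):
            raise ValueError("truth must be 'malignant' or 'benign'")
        expected = truth_for_class(self.class_label)
        if expected is not None and expected != self.truth:
            raise ValueError(
                f"class {self.class_label!r} implies truth {expected!r}, got {self.truth!r}")
        for key in ("I_D", "I_f", "I_ADC", "I_Df"):
            if key in self.means and not 0 <= self.means[key] <= 100:
                raise ValueError(f"{key} mean must be a percentage in [0, 100]")


@dataclass(frozen=True)
class VisualSurrogate:
    """Quantitative stand-in for the four-point visual dominance rating."""

    red_fraction: float
    rating: str

    @property
    def is_malignant(self) -> bool:
        """Majority rule: malignant iff more than half of the voxels are red."""
        return self.red_fraction > 50.0

    @property
    def is_definite(self) -> bool:
        return self.rating.startswith("definitely")


def truth_for_class(class_label: str) -> str | None:
    if class_label in MALIGNANT_CLASSES:
        return "malignant"
    if class_label in BENIGN_CLASSES:
        return "benign"
    return None


def roi_mean(map_: ParameterMap | IndexMap, roi: ROIMask) -> float:
    """Arithmetic mean of a map over the analysed, valid ROI voxels.

    For an index map this is the percent-red score: 100 x (red fraction).
    """
    if map_.shape != roi.mask.shape:
        raise ValueError("map and ROI must share a grid")
    sel = roi.analysed() & map_.valid
    if not sel.any():
        raise EmptyROIError(
            f"lesion {roi.lesion_id}: no valid voxels left in the analysed ROI")
    return float(np.mean(np.asarray(map_.values, dtype=np.float64)[sel]))


def hyperintensity_mask(b800_volume: np.ndarray, reference_mask: np.ndarray,
                        k_sd: float = 2.0) -> np.ndarray:
    """Translucent-hyperintensity surrogate on the b-800 image.

    Voxels whose b-800 signal exceeds mean + k_sd * SD of a normal-liver
    reference region. A degenerate reference (zero SD) falls back to a
    strict ``> mean`` rule with a warning.
    """
    b800_volume = np.asarray(b800_volume, dtype=np.float64)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != b800_volume.shape:
        raise ValueError("reference mask must share the volume grid")
    if not reference_mask.any():
        raise ValueError("reference region is empty")
    ref = b800_volume[reference_mask]
    mean, sd = float(ref.mean()), float(ref.std(ddof=1)) if ref.size > 1 else 0.0
    if sd == 0.0:
        import warnings

        warnings.warn("degenerate reference region (SD = 0); "
                      "falling back to strict > mean", stacklevel=2)
        return b800_volume > mean
    return b800_volume > mean + k_sd * sd


def _spread(x: np.ndarray, robust: bool) -> tuple[float, float]:
    center = float(np.median(x))
    if robust:
        scale = 1.4826 * float(np.median(np.abs(x - center)))
    else:
        scale = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return center, scale


def exclusion_mask(b0_volume: np.ndarray, b800_volume: np.ndarray, roi: ROIMask,
                   k_sd: float = 2.0, robust: bool = False) -> np.ndarray:
    """Necrosis/cyst/scar exclusion inside a ROI.

    Excluded voxels are hyperintense on b-0 (signal above the ROI median
    + k_sd * spread) and/or hypointense on b-800 (below the ROI median -
    k_sd * spread); the union never exceeds the ROI. The visual criterion
    of the reading protocol is quantified here as median +/- k*SD (or
    median +/- k*1.4826*MAD with ``robust=True``).
    """
    b0_volume = np.asarray(b0_volume, dtype=np.float64)
    b800_volume = np.asarray(b800_volume, dtype=np.float64)
    roi_sel = roi.mask
    b0_c, b0_s = _spread(b0_volume[roi_sel], robust)
    b8_c, b8_s = _spread(b800_volume[roi_sel], robust)
    hyper_b0 = b0_volume > b0_c + k_sd * b0_s
    hypo_b800 = b800_volume < b8_c - k_sd * b8_s
    return (hyper_b0 | hypo_b800) & roi_sel


def classify_lesion_quantitative(record: LesionRecord, cutoffs: CutoffSet,
                                 rule: str = "Df_means",
                                 pct_cutoffs: dict[str, float] = INDEX_PCT_CUTOFFS,
                                 ) -> str:
    """Malignancy call from ROI means under one of the published rules.

    * ``Df_means``  — malignant iff mean D' < c_D AND mean f' < c_f;
    * ``adc_mean``  — malignant iff mean ADC < c_ADC;
    * ``index_pct`` — malignant iff percent-red of I_Df > its cutoff
      (higher percentage = more positive test; ties are benign, mirroring
      the strict-less voxel rule);
    * ``iadc_pct``  — as index_pct for I_ADC.
    """

    def need(key: str) -> float:
        try:
            return record.means[key]
        except KeyError:
            raise ValueError(f"lesion {record.lesion_id}: missing ROI mean {key!r}") from None

    if rule == "Df_means":
        malignant = need("Dprime") < cutoffs.c_D and need("fprime") < cutoffs.c_f
    elif rule == "adc_mean":
        malignant = need("ADC") < cutoffs.c_ADC
    elif rule == "index_pct":
        malignant = need("I_Df") > pct_cutoffs["I_Df"]
    elif rule == "iadc_pct":
        malignant = need("I_ADC") > pct_cutoffs["I_ADC"]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return "malignant" if malignant else "benign"


def visual_surrogate(red_fraction: float,
                     bands: tuple[float, float, float] = (25.0, 50.0, 75.0),
                     ) -> VisualSurrogate:
    """Map a percent-red score to the four-point dominance scale.

    Default bands: >= 75 definitely malignant; (50, 75) probably
    malignant; (25, 50] probably benign; <= 25 definitely benign. Only
    the 50% majority split is anchored in the study; the outer band edges
    are a convention of this package.
    """
    if not 0 <= red_fraction <= 100:
        raise ValueError("red_fraction must be in [0, 100]")
    lo, mid, hi = bands
    if not lo < mid < hi:
        raise ValueError("bands must be strictly increasing")
    if red_fraction >= hi:
        rating = "definitely_malignant"
    elif red_fraction > mid:
        rating = "probably_malignant"
    elif red_fraction > lo:
        rating = "probably_benign"
    else:
        rating = "definitely_benign"
    return VisualSurrogate(float(red_fraction), rating)


def roi_from_lesion(scene: PhantomScene, lesion_id: int,
                    single_slice: bool = True) -> ROIMask:
    """Central single-slice ROI of a ground-truth phantom lesion.

    Takes the lesion's voxels on its centre slice (the whole lesion with
    ``single_slice=False``), emulating a centrally placed 2-D ROI.
    """
    entry = next((e for e in scene.lesion_table if e.lesion_id == lesion_id), None)
    if entry is None:
        raise KeyError(f"scene has no lesion {lesion_id}")
    mask = scene.lesion_mask(lesion_id)
    if single_slice:
        z = entry.center[2]
        keep = np.zeros_like(mask)
        keep[:, :, z] = mask[:, :, z]
        mask = keep
        return ROIMask(lesion_id, mask, slice_index=z)
    return ROIMask(lesion_id, mask, slice_index=None)
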