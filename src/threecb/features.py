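"""Concentric-ring ROI construction and compositional feature extraction.

Each lesion ROI is surrounded by three 2-mm-wide outer rings (0-2, 2-4 and
4-6 mm from the lesion border, measured by the Euclidean distance transform of
the lesion complement).  Nine statistics (mean, median, standard deviation,
minimum, maximum, kurtosis, skew, total, percentage) are computed per region
on each of the three component thickness maps, giving 9 x 4 x 3 = 108
compositional features per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import convex_hull_image

from .decomposition import LWPMaps
from .exceptions import InputError

COMPONENTS = ("lipid", "water", "protein")
REGIONS = ("lesion", "ring1", "ring2", "ring3")
STATISTICS = (
    "mean",
    "median",
    "sd",
    "min",
    "max",
    "kurtosis",
    "skew",
    "total",
    "percentage",
)

#: Fixed 108-feature schema in (component, region, statistic) order.
FEATURE_NAMES = tuple(
    f"{comp}_{region}_{stat}"
    for comp in COMPONENTS
    for region in REGIONS
    for stat in STATISTICS
)

RING_WIDTH_MM = 2.0
N_RINGS = 3


@dataclass
class RoiRegions:
    """A lesion mask plus its three concentric 2-mm outer rings.

    Ring k holds the pixels outside the lesion whose Euclidean distance to the
    lesion lies in ``(2(k-1), 2k]`` mm, clipped to the breast mask (and, by
    default, excluding pixels belonging to any other lesion).  The four masks
    are pairwise disjoint; empty rings are permitted and flagged.
    """

    lesion_mask: np.ndarray
    ring_masks: tuple
    pixel_spacing: float
    empty_rings: tuple = (False, False, False)


def make_outer_rings(
    lesion_mask: np.ndarray,
    breast_mask: np.ndarray,
    pixel_spacing: float,
    exclude_masks: list | None = None,
) -> RoiRegions:
    """Build the three 2-mm outer rings of a lesion from the distance transform.

    ``exclude_masks`` (e.g. other lesions on the same view) are removed from
    the rings so that "background" regions are not contaminated by a second
    lesion.
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    breast = np.asarray(breast_mask, dtype=bool)
    if lesion.shape != breast.shape:
        raise InputError("lesion and breast masks must share one shape")
    if not lesion.any():
        raise InputError("lesion mask is empty")
    if pixel_spacing <= 0 or pixel_spacing > 1.0:
        raise InputError("pixel spacing must be in (0, 1] mm for 2-mm rings")

    dist_mm = ndimage.distance_transform_edt(~lesion, sampling=pixel_spacing)
    allowed = breast & ~lesion
    if exclude_masks:
        for m in exclude_masks:
            allowed &= ~np.asarray(m, dtype=bool)
    rings = []
    for k in range(1, N_RINGS + 1):
        lo, hi = RING_WIDTH_MM * (k - 1), RING_WIDTH_MM * k
        rings.append((dist_mm > lo) & (dist_mm <= hi) & allowed)
    return RoiRegions(
        lesion_mask=lesion,
        ring_masks=tuple(rings),
        pixel_spacing=float(pixel_spacing),
        empty_rings=tuple(not r.any() for r in rings),
    )


@dataclass
class RegionStats:
    """The nine per-region statistics of one component's pixel thicknesses.

    ``percentage`` is the region-level share of this component in the total
    lipid+water+protein thickness of the region (the three components'
    percentages sum to 100).  Empty regions yield a missing-value record;
    single-pixel or constant regions report sd = 0 and kurtosis/skew = 0 with
    the degenerate flag set.
    """

    mean: float
    median: float
    sd: float
    min: float
    max: float
    kurtosis: float
    skew: float
    total: float
    percentage: float
    n_pixels: int
    empty: bool = False
    degenerate: bool = False

    def as_tuple(self) -> tuple:
        return (self.mean, self.median, self.sd, self.min, self.max,
                self.kurtosis, self.skew, self.total, self.percentage)


def _empty_stats() -> RegionStats:
    nan = float("nan")
    return RegionStats(nan, nan, nan, nan, nan, nan, nan, nan, nan,
                       n_pixels=0, empty=True)


def region_stats(
    component_map: np.ndarray,
    region_mask: np.ndarray,
    all_components_total: float,
) -> RegionStats:
    """Sample statistics of one component over one region.

    ``all_components_total`` is the summed lipid+water+protein thickness over
    the same region, used as the percentage denominator.  Kurtosis is Fisher
    excess and skew the adjusted Fisher-Pearson coefficient (both
    bias-corrected); the standard deviation uses the n-1 sample convention.
    """
    mask = np.asarray(region_mask, dtype=bool)
    vals = np.asarray(component_map, dtype=float)[mask]
    n = vals.size
    if n == 0:
        return _empty_stats()
    total = float(vals.sum())
    if all_components_total > 0:
        pct = 100.0 * total / all_components_total
    else:
        pct = float("nan")
    if n == 1 or np.ptp(vals) == 0.0:
        v = float(vals[0])
        return RegionStats(
            mean=float(vals.mean()), median=float(np.median(vals)), sd=0.0,
            min=float(vals.min()), max=float(vals.max()),
            kurtosis=0.0, skew=0.0, total=total, percentage=pct,
            n_pixels=n, degenerate=True,
        )
    return RegionStats(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        sd=float(vals.std(ddof=1)),
        min=float(vals.min()),
        max=float(vals.max()),
        kurtosis=float(stats.kurtosis(vals, fisher=True, bias=False)),
        skew=float(stats.skew(vals, bias=False)),
        total=total,
        percentage=pct,
        n_pixels=n,
    )


@dataclass
class LesionFeatureRecord:
    """One ROI's 108 compositional features plus its CAD probability and label.

    The label maps pathology exactly as {BN, FA} -> 0 and {DCIS, IDC} -> 1.
    """

    features: dict
    cad_probability: float
    label: int
    patient_id: str
    roi_source: str  # "radiologist" | "CAD"
    pathology: str = ""
    receptor_status: str = "none"
    lesion_id: str = ""
    cad_missed: bool = False

    def __post_init__(self) -> None:
        if tuple(self.features) != FEATURE_NAMES:
            raise InputError(
                f"feature record must carry exactly the {len(FEATURE_NAMES)} "
                "named compositional features in schema order"
            )


def pathology_label(pathology: str) -> int:
    mapping = {"BN": 0, "FA": 0, "DCIS": 1, "IDC": 1}
    try:
        return mapping[pathology]
    except KeyError:
        raise InputError(f"unknown pathology {pathology!r}") from None


def extract_feature_vector(
    lwp: LWPMaps,
    regions: RoiRegions,
    cad_probability: float,
    label: int,
    patient_id: str,
    roi_source: str = "radiologist",
    pathology: str = "",
    receptor_status: str = "none",
    lesion_id: str = "",
    cad_missed: bool = False,
) -> LesionFeatureRecord:
    """Compute the fixed 108-feature vector for one ROI.

    Feature order is (component, region, statistic) with deterministic names
    ``comp_region_stat``.  Raises :class:`InputError` when the lesion and all
    rings are empty.
    """
    masks = {"lesion": regions.lesion_mask}
    for k in range(N_RINGS):
        masks[f"ring{k + 1}"] = regions.ring_masks[k]
    if not any(m.any() for m in masks.values()):
        raise InputError("lesion and all rings are empty")

    comp_maps = {c: lwp.component(c) for c in COMPONENTS}
    totals = {
        region: float(sum(comp_maps[c][mask].sum() for c in COMPONENTS))
        for region, mask in masks.items()
    }
    feats: dict[str, float] = {}
    for comp in COMPONENTS:
        for region in REGIONS:
            rs = region_stats(comp_maps[comp], masks[region], totals[region])
            for stat, value in zip(STATISTICS, rs.as_tuple()):
                feats[f"{comp}_{region}_{stat}"] = value
    return LesionFeatureRecord(
        features=feats,
        cad_probability=float(cad_probability),
        label=int(label),
        patient_id=patient_id,
        roi_source=roi_source,
        pathology=pathology,
        receptor_status=receptor_status,
        lesion_id=lesion_id,
        cad_missed=cad_missed,
    )


def filter_cad_proposals(
    proposals: list,
    radiologist_rois: list,
    overlap_threshold: float = 0.25,
) -> list:
    """Keep CAD proposals overlapping a radiologist ROI by >= the threshold.

    Overlap is measured as ``|proposal & roi| / |proposal|`` (the proposal's
    own area is the denominator).  Each included proposal is matched to the
    ROI with maximal overlap fraction, ties broken by larger intersection then
    lowest ROI index, and inherits that ROI's pathology.  Returns a list of
    ``(proposal, roi_index)`` pairs; non-overlapping proposals are dropped.
    """
    included = []
    for prop in proposals:
        pmask = np.asarray(prop.mask, dtype=bool)
        area = pmask.sum()
        if area == 0:
            continue
        best = None  # (fraction, intersection, -index)
        best_idx = None
        for idx, roi in enumerate(radiologist_rois):
            roi_mask = np.asarray(
                roi.mask if hasattr(roi, "mask") else roi, dtype=bool
            )
            if roi_mask.shape != pmask.shape:
                raise InputError("proposal and ROI masks must share one grid")
            inter = int((pmask & roi_mask).sum())
            frac = inter / area
            key = (frac, inter, -idx)
            if best is None or key > best:
                best, best_idx = key, idx
        if best is not None and best[0] >= overlap_threshold:
            included.append((prop, best_idx))
    return included


def calcification_cluster_hull(point_masks: list) -> np.ndarray:
    """Filled convex hull of a calcification cluster, on the image grid.

    The cluster ROI is the minimum convex envelope containing all member
    calcification pixels.
    """
    if not point_masks:
        raise InputError("need at least one calcification mask")
    union = np.zeros(np.asarray(point_masks[0]).shape, dtype=bool)
    for m in point_masks:
        mm = np.asarray(m, dtype=bool)
        if mm.shape != union.shape:
            raise InputError("calcification masks must share one grid")
        union |= mm
    if not union.any():
        raise InputError("calcification masks are all empty")
    return convex_hull_image(union)


def records_to_frame(records: list) -> "pandas.DataFrame":
    """Stack LesionFeatureRecords into the canonical feature table."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "lesion_id": r.lesion_id,
            "roi_source": r.roi_source,
            "pathology": r.pathology,
            "receptor_status": r.receptor_status,
            "label": r.label,
            "cad_probability": r.cad_probability,
            "cad_missed": r.cad_missed,
        }
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)
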