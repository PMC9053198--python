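"""Lesion-minus-background compositional signatures and group comparisons.

A lesion's compositional signature with respect to outer ring k is the median
component thickness over the lesion pixels minus the median over the ring
pixels.  Medians (rather than means) damp the influence of microcalcification
pixels, which produce spuriously high water/protein signal.  Signatures are
stratified by pathology and, among invasive lesions, by hormone-receptor
status; group differences are tested per (component, ring) cell with Welch's
unequal-variance t-test on the per-lesion signature values (lesions are the
independent units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import LWPMaps
from .exceptions import InputError
from .features import COMPONENTS, N_RINGS, RoiRegions

MALIGNANT_PATHOLOGIES = ("DCIS", "IDC")
BENIGN_PATHOLOGIES = ("BN", "FA")


@dataclass(frozen=True)
class SignatureRecord:
    """median(component over lesion) - median(component over ring), in cm."""

    lesion_id: str
    patient_id: str
    component: str
    ring: int  # 1, 2, 3
    signature: float
    pathology: str
    receptor_status: str = "none"
    empty_ring: bool = False


def compute_signatures(
    lwp: LWPMaps,
    regions: RoiRegions,
    lesion_id: str = "",
    patient_id: str = "",
    pathology: str = "",
    receptor_status: str = "none",
) -> list:
    """Nine signature records per lesion (3 components x 3 rings).

    Medians are taken over the raw (unclipped) thickness values.  Empty rings
    yield a flagged record with a NaN signature rather than a crash.
    """
    lesion = regions.lesion_mask
    if not lesion.any():
        raise InputError("lesion region is empty")
    records = []
    for comp in COMPONENTS:
        cmap = lwp.component(comp)
        lesion_median = float(np.median(cmap[lesion]))
        for k in range(N_RINGS):
            ring = regions.ring_masks[k]
            if ring.any():
                sig = lesion_median - float(np.median(cmap[ring]))
                empty = False
            else:
                sig, empty = float("nan"), True
            records.append(
                SignatureRecord(
                    lesion_id=lesion_id,
                    patient_id=patient_id,
                    component=comp,
                    ring=k + 1,
                    signature=sig,
                    pathology=pathology,
                    receptor_status=receptor_status,
                    empty_ring=empty,
                )
            )
    return records


def signatures_to_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(sample_a, sample_b) -> WelchResult:
    """Two-sample t-test without the equal-variance assumption.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.  Each
    sample needs at least two values; two degenerate samples with equal means
    return t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InputError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return WelchResult(0.0, df, 1.0)
        t = np.inf if diff > 0 else -np.inf
        return WelchResult(float(t), df, float(np.nextafter(0.0, 1.0)))
    se2_a, se2_b = va / na, vb / nb
    se2 = se2_a + se2_b
    t = diff / np.sqrt(se2)
    df = se2**2 / (se2_a**2 / (na - 1) + se2_b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(max(p, np.nextafter(0.0, 1.0)), 1.0)))


@dataclass
class GroupComparison:
    """One (component, ring) cell of a two-group signature comparison."""

    component: str
    ring: int
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    median_difference: float  # group A minus group B
    t: float
    df: float
    p: float
    skipped: bool = False


def _group_rule(grouping: str):
    if grouping == "malignancy":
        return (
            "malignant",
            "benign",
            lambda r: r["pathology"].isin(MALIGNANT_PATHOLOGIES),
            lambda r: r["pathology"].isin(BENIGN_PATHOLOGIES),
        )
    if grouping == "receptor":
        idc = lambda r: r["pathology"] == "IDC"  # noqa: E731
        return (
            "triple-negative",
            "receptor-positive",
            lambda r: idc(r) & (r["receptor_status"] == "triple-negative"),
            lambda r: idc(r)
            & r["receptor_status"].isin(
                ["ER+", "PR+", "HER2+", "ER+/PR+", "ER+/PR+/HER2+"]
            ),
        )
    raise InputError(f"unknown grouping rule {grouping!r}")


def compare_groups(records, grouping: str = "malignancy") -> list:
    """Per-(component, ring) group medians, median difference, and Welch test.

    ``grouping='malignancy'`` compares malignant (DCIS+IDC) against benign
    (BN+FA) lesions; ``grouping='receptor'`` compares triple-negative against
    any-receptor-positive lesions among invasive cancers only.  The median
    difference is group A minus group B (malignant minus benign), so lipid
    differences come out negative for the default cohort.  Cells with an empty
    group are skipped with a flag.
    """
    frame = records if isinstance(records, pd.DataFrame) else signatures_to_frame(records)
    name_a, name_b, rule_a, rule_b = _group_rule(grouping)
    frame = frame[~frame["empty_ring"].astype(bool)]
    out = []
    for comp in COMPONENTS:
        for ring in range(1, N_RINGS + 1):
            cell = frame[(frame["component"] == comp) & (frame["ring"] == ring)]
            a = cell[rule_a(cell)]["signature"].to_numpy(dtype=float)
            b = cell[rule_b(cell)]["signature"].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                out.append(
                    GroupComparison(
                        component=comp, ring=ring, group_a=name_a, group_b=name_b,
                        n_a=len(a), n_b=len(b),
                        median_a=float("nan"), median_b=float("nan"),
                        median_difference=float("nan"),
                        t=float("nan"), df=float("nan"), p=float("nan"),
                        skipped=True,
                    )
                )
                continue
            res = welch_test(a, b)
            med_a, med_b = float(np.median(a)), float(np.median(b))
            out.append(
                GroupComparison(
                    component=comp, ring=ring, group_a=name_a, group_b=name_b,
                    n_a=len(a), n_b=len(b),
                    median_a=med_a, median_b=med_b,
                    median_difference=med_a - med_b,
                    t=res.t, df=res.df, p=res.p,
                )
            )
    return out


def comparisons_to_frame(comparisons: list) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def box_summary(values) -> dict:
    """Quartiles and 1.5-IQR whiskers for box-plot style exports."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {k: float("nan") for k in
                ("q1", "median", "q3", "whisker_low", "whisker_high")}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi)}
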