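"""Added-diagnostic-value metrics: ROC/AUC, bootstrap CIs, IDI and NRI.

Given per-ROI malignancy labels and probabilities from a reference model
(CAD alone) and a new model (CAD plus compositional features), this module
quantifies the new model's added value:

* AUC by the rank method (ties counted 1/2), with seeded bootstrap percentile
  confidence intervals;
* the integrated discrimination improvement IDI = IS + IP, where IS is the
  change in mean predicted risk among events and IP the change (reference
  minus new) among non-events, reported in percentage points;
* categorical net reclassification improvement over the BI-RADS risk bins
  3 / 4a / 4b / 4c&5 (upper-inclusive intervals at 2, 10 and 50 %), and binary
  NRI at each BI-RADS border threshold (2, 10, 50, 95 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import InputError, UndefinedMetricError

BIRADS_LABELS = ("3", "4a", "4b", "4c&5")


@dataclass(frozen=True)
class BiradsBins:
    """BI-RADS risk bins: upper-inclusive intervals partitioning (0, 1].

    Category 3 is (0, 0.02] (probability 0 also maps to 3), 4a is
    (0.02, 0.10], 4b is (0.10, 0.50] and 4c&5 is (0.50, 1].  The border set for
    the binary analyses additionally includes the 4c/5 border at 0.95.
    """

    upper_edges: tuple = (0.02, 0.10, 0.50, 1.0)
    labels: tuple = BIRADS_LABELS
    borders: tuple = (0.02, 0.10, 0.50, 0.95)

    def __post_init__(self) -> None:
        if list(self.borders) != sorted(self.borders):
            raise InputError("borders must be strictly increasing")
        if len(self.upper_edges) != len(self.labels):
            raise InputError("one upper edge per category is required")


@dataclass
class RiskPair:
    """Labels plus paired reference/new model probabilities per ROI."""

    labels: np.ndarray
    p_ref: np.ndarray
    p_new: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.p_ref = np.asarray(self.p_ref, dtype=float)
        self.p_new = np.asarray(self.p_new, dtype=float)
        if not (len(self.labels) == len(self.p_ref) == len(self.p_new)):
            raise InputError("labels, p_ref and p_new must have equal lengths")
        for p in (self.p_ref, self.p_new):
            if ((p < 0) | (p > 1)).any():
                raise InputError("probabilities must lie in [0, 1]")

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise UndefinedMetricError("both classes are required")


def roc_auc(labels, scores) -> float:
    """AUC by the rank/trapezoid method with tied scores counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC is undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for CSV export."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC is undefined for single-class labels")
    fpr, tpr, thresh = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})


def bootstrap_auc_ci(
    labels,
    scores,
    n_boot: int = 1000,
    seed: int = 0,
    patient_ids=None,
    patient_level: bool = False,
) -> tuple[float, float, float]:
    """Bootstrap mean AUC with a 2.5-97.5 percentile interval.

    Resampling is at ROI level by default (``patient_level=True`` resamples
    whole patients instead, acknowledging within-patient correlation).
    Resamples lacking one of the classes are redrawn.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC is undefined for single-class labels")
    rng = np.random.default_rng(seed)
    n = len(labels)
    aucs = np.empty(n_boot)
    if patient_level:
        if patient_ids is None:
            raise InputError("patient_level resampling requires patient_ids")
        pids = np.asarray(patient_ids)
        uniq = np.unique(pids)
        groups = {p: np.flatnonzero(pids == p) for p in uniq}
    for b in range(n_boot):
        for _redraw in range(1000):
            if patient_level:
                chosen = rng.choice(uniq, size=len(uniq), replace=True)
                idx = np.concatenate([groups[p] for p in chosen])
            else:
                idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) > 1:
                break
        else:  # pragma: no cover - essentially impossible with both classes
            raise UndefinedMetricError("could not draw a two-class resample")
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    return (
        float(aucs.mean()),
        float(np.percentile(aucs, 2.5)),
        float(np.percentile(aucs, 97.5)),
    )


def idi_components(pair: RiskPair) -> tuple[float, float, float]:
    """Integrated sensitivity, integrated 1-specificity, and their sum (IDI).

    IS = mean(p_new | events) - mean(p_ref | events);
    IP = mean(p_ref | non-events) - mean(p_new | non-events);
    all three reported in percentage points (x100).
    """
    pair.require_both_classes()
    ev = pair.labels == 1
    is_ = pair.p_new[ev].mean() - pair.p_ref[ev].mean()
    ip = pair.p_ref[~ev].mean() - pair.p_new[~ev].mean()
    return 100.0 * float(is_), 100.0 * float(ip), 100.0 * float(is_ + ip)


def assign_birads_category(probability: float, bins: BiradsBins | None = None) -> str:
    """Upper-inclusive binning; probability 0 maps to category 3."""
    bins = bins or BiradsBins()
    p = float(probability)
    if not 0.0 <= p <= 1.0:
        raise InputError("probability must lie in [0, 1]")
    for edge, label in zip(bins.upper_edges, bins.labels):
        if p <= edge:
            return label
    return bins.labels[-1]


def _categories(probs: np.ndarray, bins: BiradsBins) -> np.ndarray:
    edges = np.asarray(bins.upper_edges[:-1])
    return np.searchsorted(edges, probs, side="left")  # index into labels


@dataclass
class ReclassificationReport:
    """Cross-tabulated risk-category movement plus NRI and IDI components.

    ``events_table`` and ``nonevents_table`` are reference-category (rows) by
    new-category (columns) counts; margins equal the per-class counts.
    ``nri_total = nri_events + nri_nonevents``.
    """

    events_table: pd.DataFrame
    nonevents_table: pd.DataFrame
    nri_events: float
    nri_nonevents: float
    nri_total: float
    per_border: dict
    integrated_sensitivity: float
    integrated_one_minus_specificity: float
    idi: float
    bins: BiradsBins = field(default_factory=BiradsBins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "events_table": self.events_table.to_dict(),
                "nonevents_table": self.nonevents_table.to_dict(),
                "nri_events": self.nri_events,
                "nri_nonevents": self.nri_nonevents,
                "nri_total": self.nri_total,
                "per_border": {str(k): v for k, v in self.per_border.items()},
                "integrated_sensitivity": self.integrated_sensitivity,
                "integrated_one_minus_specificity":
                    self.integrated_one_minus_specificity,
                "idi": self.idi,
            },
            indent=2,
        )

    def text_table(self) -> str:
        lines = ["Events (reference rows x new columns)"]
        lines.append(self.events_table.to_string())
        lines.append("")
        lines.append("Non-events (reference rows x new columns)")
        lines.append(self.nonevents_table.to_string())
        lines.append("")
        lines.append(
            f"NRI events = {self.nri_events:+.4f}, "
            f"non-events = {self.nri_nonevents:+.4f}, "
            f"total = {self.nri_total:+.4f}"
        )
        lines.append(
            f"IS = {self.integrated_sensitivity:+.2f} pp, "
            f"IP = {self.integrated_one_minus_specificity:+.2f} pp, "
            f"IDI = {self.idi:+.2f} pp"
        )
        return "\n".join(lines)


def _nri_from_categories(ref_cat, new_cat, mask) -> tuple[float, int, int, int]:
    up = int((new_cat[mask] > ref_cat[mask]).sum())
    down = int((new_cat[mask] < ref_cat[mask]).sum())
    n = int(mask.sum())
    return up, down, n


def categorical_nri(pair: RiskPair, bins: BiradsBins | None = None) -> ReclassificationReport:
    """Events/non-events cross-tables over the BI-RADS bins, with NRI and IDI.

    NRI_events counts events moving to a higher risk category minus those
    moving lower, over the number of events; NRI_nonevents counts non-events
    moving lower minus moving higher, over the number of non-events.
    """
    bins = bins or BiradsBins()
    pair.require_both_classes()
    ref_cat = _categories(pair.p_ref, bins)
    new_cat = _categories(pair.p_new, bins)
    ev = pair.labels == 1

    k = len(bins.labels)
    tables = {}
    for name, mask in (("events", ev), ("nonevents", ~ev)):
        tab = np.zeros((k, k), dtype=int)
        np.add.at(tab, (ref_cat[mask], new_cat[mask]), 1)
        tables[name] = pd.DataFrame(tab, index=list(bins.labels),
                                    columns=list(bins.labels))

    up_e, down_e, n_e = _nri_from_categories(ref_cat, new_cat, ev)
    up_n, down_n, n_n = _nri_from_categories(ref_cat, new_cat, ~ev)
    nri_e = (up_e - down_e) / n_e
    nri_n = (down_n - up_n) / n_n

    is_, ip, idi = idi_components(pair)
    per_border = {b: binary_nri_at_threshold(pair, b) for b in bins.borders}
    return ReclassificationReport(
        events_table=tables["events"],
        nonevents_table=tables["nonevents"],
        nri_events=float(nri_e),
        nri_nonevents=float(nri_n),
        nri_total=float(nri_e + nri_n),
        per_border=per_border,
        integrated_sensitivity=is_,
        integrated_one_minus_specificity=ip,
        idi=idi,
        bins=bins,
    )


def binary_nri_at_threshold(pair: RiskPair, threshold: float) -> tuple[float, float, float]:
    """Two-category NRI after dichotomizing both models at one threshold.

    Positive means probability strictly above the threshold (threshold 0 is
    accepted as a degenerate case where nothing can reclassify downward of it).
    Returns (NRI_events, NRI_nonevents, NRI_total).
    """
    if not 0.0 <= threshold < 1.0:
        raise InputError("threshold must lie in [0, 1)")
    pair.require_both_classes()
    ev = pair.labels == 1
    ref_pos = pair.p_ref > threshold
    new_pos = pair.p_new > threshold
    up = new_pos & ~ref_pos
    down = ~new_pos & ref_pos
    n_e = int(ev.sum())
    n_n = int((~ev).sum())
    nri_e = (int((up & ev).sum()) - int((down & ev).sum())) / n_e
    nri_n = (int((down & ~ev).sum()) - int((up & ~ev).sum())) / n_n
    return float(nri_e), float(nri_n), float(nri_e + nri_n)
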