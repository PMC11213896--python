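"""Ratio-based clinical indexes for detecting the inflammatory subtype.

Each index is a numerator/denominator analyte pair drawn from (possibly
different) layers.  The cutoff is a percentile of the ratio in euploid
controls; a sample is called positive when its ratio exceeds the cutoff.
Sensitivity is computed over the target-subtype samples and specificity
over the remaining trisomic samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RatioIndex", "IndexReport", "ClassifierReport",
           "percentile_cutoff", "compute_ratio", "evaluate_index", "combine_indexes"]


@dataclass(frozen=True)
class RatioIndex:
    """Definition of one ratio index (cutoff attached after derivation)."""

    name: str
    numerator_layer: str
    numerator: str
    denominator_layer: str
    denominator: str
    pct: float = 90.0
    cutoff: float | None = None


@dataclass
class IndexReport:
    """Per-sample ratios and calls for one index, with confusion metrics."""

    index: RatioIndex
    ratios: pd.Series
    calls: pd.Series          # bool, positive = above cutoff
    truth: pd.Series          # bool, True = target subtype
    sensitivity: float = np.nan
    specificity: float = np.nan
    confusion: dict = field(default_factory=dict)


@dataclass
class ClassifierReport:
    indexes: list
    combined: IndexReport | None = None
    rule: str = "all-positive"


def percentile_cutoff(control_values, pct: float = 90.0, min_n: int = 10) -> float:
    """pct-th percentile of control ratios (linear interpolation, type 7)."""
    vals = np.asarray(list(control_values), float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_n:
        raise ValueError(f"need >= {min_n} control values for a stable cutoff, got {len(vals)}")
    if not (0 <= pct <= 100):
        raise ValueError("pct must be in [0, 100]")
    return float(np.percentile(vals, pct))


def compute_ratio(idx: RatioIndex, layers: dict, samples) -> pd.Series:
    """Numerator/denominator ratio per sample; non-positive denominators are
    excluded (NaN) with a log message."""
    for layer_name, analyte in ((idx.numerator_layer, idx.numerator),
                                (idx.denominator_layer, idx.denominator)):
        if layer_name not in layers:
            raise KeyError(f"layer {layer_name!r} not provided")
        if analyte not in layers[layer_name].feature_ids:
            raise KeyError(f"analyte {analyte!r} absent from layer {layer_name!r}")
    num = layers[idx.numerator_layer].values.loc[idx.numerator]
    den = layers[idx.denominator_layer].values.loc[idx.denominator]
    samples = list(samples)
    num = num.reindex(samples)
    den = den.reindex(samples)
    bad = ~(den > 0)
    if bad.any():
        logger.info("index %s: excluding %d samples with non-positive denominator",
                    idx.name, int(bad.sum()))
    ratio = num / den.where(~bad)
    return ratio.rename(idx.name)


def evaluate_index(idx: RatioIndex, layers: dict, truth: pd.Series,
                   control_ids, pct: float | None = None) -> IndexReport:
    """Derive the control-percentile cutoff and score one index.

    ``truth`` maps each evaluated (trisomic) sample to True for the target
    subtype; ``control_ids`` are the euploid samples defining the cutoff.
    Sensitivity = called positives among target samples; specificity =
    called negatives among non-target trisomic samples.
    """
    pct = idx.pct if pct is None else pct
    control_ratio = compute_ratio(idx, layers, control_ids).dropna()
    cutoff = percentile_cutoff(control_ratio, pct)
    idx = RatioIndex(idx.name, idx.numerator_layer, idx.numerator,
                     idx.denominator_layer, idx.denominator, pct, cutoff)

    eval_ids = list(truth.index)
    ratios = compute_ratio(idx, layers, eval_ids)
    if truth.isna().any():
        missing = list(truth.index[truth.isna()])
        raise ValueError(f"truth labels missing for samples: {missing[:5]}")
    usable = ratios.notna()
    calls = (ratios > cutoff) & usable
    report = IndexReport(index=idx, ratios=ratios, calls=calls[usable],
                         truth=truth[usable].astype(bool))
    _fill_metrics(report)
    return report


def _fill_metrics(report: IndexReport) -> None:
    t = report.truth
    c = report.calls.reindex(t.index)
    tp = int((c & t).sum())
    fn = int((~c & t).sum())
    fp = int((c & ~t).sum())
    tn = int((~c & ~t).sum())
    report.confusion = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
    report.sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    report.specificity = tn / (tn + fp) if (tn + fp) else np.nan


def combine_indexes(reports: list, rule: str = "all-positive") -> IndexReport:
    """Combine component indexes into one classifier.

    "all-positive": positive only if every component index is positive (AND);
    "majority": positive if more than half the components are positive.  All
    components must cover the same sample set.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 component indexes")
    base = list(reports[0].calls.index)
    for r in reports[1:]:
        if list(r.calls.index) != base:
            raise ValueError("component indexes cover different samples")
    calls_matrix = pd.concat([r.calls.rename(r.index.name) for r in reports], axis=1)
    if rule == "all-positive":
        combined_calls = calls_matrix.all(axis=1)
    elif rule == "majority":
        combined_calls = calls_matrix.sum(axis=1) > (len(reports) / 2)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    combo = IndexReport(
        index=RatioIndex(name=f"combined[{rule}]", numerator_layer="", numerator="",
                         denominator_layer="", denominator=""),
        ratios=pd.Series(np.nan, index=base),
        calls=combined_calls,
        truth=reports[0].truth,
    )
    _fill_metrics(combo)
    if rule == "all-positive":
        # exact set-theoretic guarantees of the AND rule
        assert all(combo.specificity >= r.specificity - 1e-12 for r in reports)
        assert all(combo.sensitivity <= r.sensitivity + 1e-12 for r in reports)
    return combo
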