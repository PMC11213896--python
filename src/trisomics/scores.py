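"""Composite z-score biomarkers: polygenic cluster scores and cytokine score."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ZScoreMatrix
from .stats import DifferentialResult

logger = logging.getLogger(__name__)

__all__ = ["CompositeScore", "polygenic_score", "select_score_analytes", "cytokine_score"]


@dataclass
class CompositeScore:
    """Per-sample sum of z-scores over a declared component feature list.

    ``completeness`` is the fraction of components observed per sample;
    samples with missing components keep a score over the available
    components but are flagged rather than silently dropped.
    """

    values: pd.Series
    components: tuple
    reference: tuple
    name: str = "score"
    n_available: pd.Series | None = None

    @property
    def completeness(self) -> pd.Series:
        if self.n_available is None:
            return pd.Series(1.0, index=self.values.index)
        return self.n_available / len(self.components)

    @property
    def flagged(self) -> pd.Index:
        """Samples whose score was computed over an incomplete component set."""
        return self.values.index[self.completeness < 1.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "score_name": self.name,
            "value": self.values,
            "n_components": (self.completeness * len(self.components)).astype(int),
            "completeness": self.completeness,
        })


def _sum_z(z: ZScoreMatrix, features, name: str) -> CompositeScore:
    missing = [f for f in features if f not in z.z.index]
    if missing:
        raise KeyError(f"score components absent from z-matrix: {missing[:5]}")
    block = z.z.loc[list(features)]
    values = block.sum(axis=0, skipna=True)
    n_avail = block.notna().sum(axis=0)
    incomplete = int((n_avail < len(features)).sum())
    if incomplete:
        logger.warning("%s: %d samples flagged with missing components", name, incomplete)
    return CompositeScore(values=values.rename(name), components=tuple(features),
                          reference=tuple(z.reference), name=name, n_available=n_avail)


def polygenic_score(z: ZScoreMatrix, genes, name: str = "polygenic") -> CompositeScore:
    """Sum of expression z-scores (relative to the reference group) over a
    gene-cluster member list."""
    return _sum_z(z, genes, name)


def cytokine_score(z: ZScoreMatrix, analytes, name: str = "cytokine") -> CompositeScore:
    """Sum of panel z-scores over the selected inflammatory analytes."""
    return _sum_z(z, analytes, name)


def select_score_analytes(diff_vs_controls: DifferentialResult,
                          diff_vs_ms1: DifferentialResult,
                          fc_threshold: float = 1.0,
                          q_threshold: float = 0.1) -> list:
    """Analytes elevated in both contrasts: linear FC > fc_threshold and
    q < q_threshold in each.

    "FC > 1" is read on the linear scale, i.e. log2FC > log2(fc_threshold);
    with the default threshold of 1 any elevation qualifies and significance
    is carried by q alone.  Output is ordered by ascending q in the control
    contrast (ties by analyte id).
    """
    a = diff_vs_controls.table
    b = diff_vs_ms1.table
    if set(a.index) != set(b.index):
        raise ValueError("contrasts cover different analyte sets")
    b = b.reindex(a.index)
    log2_thr = np.log2(fc_threshold)
    hit = ((a["log2fc"] > log2_thr) & (a["q"] < q_threshold)
           & (b["log2fc"] > log2_thr) & (b["q"] < q_threshold))
    hit = hit.fillna(False)
    selected = a[hit].sort_values("q", kind="mergesort")
    ordered = sorted(selected.index, key=lambda g: (selected.loc[g, "q"], str(g)))
    if not ordered:
        warnings.warn("select_score_analytes: no analyte passed both contrasts")
    return list(ordered)
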