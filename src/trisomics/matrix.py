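"""Core tabular containers shared by every pipeline stage.

An :class:`OmicsMatrix` is a feature-by-sample grid of measurements for one
assay layer (expression, proteomics, metabolomics, ...).  Missing values are
represented as NaN; every operation downstream is expected to tolerate them
pairwise.  A :class:`ZScoreMatrix` is the same grid standardised against a
declared reference sample group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "ZScoreMatrix", "validate_sample_table"]

#: columns every sample table must carry
SAMPLE_COLUMNS = ("karyotype", "age", "sex", "source")


def _check_unique(index: pd.Index, axis: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {axis} ids: {dupes[:5]}")


@dataclass
class OmicsMatrix:
    """Numeric feature x sample matrix for a single omics layer.

    Parameters
    ----------
    values
        DataFrame with feature ids as the row index and sample ids as
        columns.  NaN marks missing/masked entries.
    layer
        Short label of the assay layer ("expression", "metabolome", ...).
    units
        Unit annotation carried through for provenance only.
    """

    values: pd.DataFrame
    layer: str = "unnamed"
    units: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        non_numeric = [
            c for c, d in self.values.dtypes.items() if not np.issubdtype(d, np.number)
        ]
        if non_numeric:
            raise ValueError(f"non-numeric columns in layer {self.layer!r}: {non_numeric[:5]}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError(f"non-finite (inf) entries in layer {self.layer!r}")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "OmicsMatrix":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise KeyError(f"features absent from layer {self.layer!r}: {missing[:5]}")
        return OmicsMatrix(self.values.loc[list(features)].copy(), self.layer, self.units)

    def subset_samples(self, samples) -> "OmicsMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from layer {self.layer!r}: {missing[:5]}")
        return OmicsMatrix(self.values[list(samples)].copy(), self.layer, self.units)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.layer, self.units)


@dataclass
class ZScoreMatrix:
    """Feature x sample z-scores relative to a reference sample group.

    ``ref_mean``/``ref_sd`` are the per-feature statistics (sample SD, n-1
    denominator) of the reference group used for standardisation, so the
    transform can be audited or inverted.
    """

    z: pd.DataFrame
    reference: tuple = ()
    ref_mean: pd.Series = field(default_factory=pd.Series)
    ref_sd: pd.Series = field(default_factory=pd.Series)
    layer: str = "unnamed"

    @property
    def feature_ids(self) -> pd.Index:
        return self.z.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.z.columns

    def subset_samples(self, samples) -> "ZScoreMatrix":
        return ZScoreMatrix(
            self.z[list(samples)].copy(), self.reference, self.ref_mean, self.ref_sd, self.layer
        )

    def subset_features(self, features) -> "ZScoreMatrix":
        missing = [f for f in features if f not in self.z.index]
        if missing:
            raise KeyError(f"features absent from z-matrix: {missing[:5]}")
        feats = list(features)
        return ZScoreMatrix(
            self.z.loc[feats].copy(),
            self.reference,
            self.ref_mean.reindex(feats),
            self.ref_sd.reindex(feats),
            self.layer,
        )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata table and return it unchanged.

    Requires a unique sample-id index plus karyotype/age/sex/source columns.
    """
    _check_unique(samples.index, "sample")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return samples
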