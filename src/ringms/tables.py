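"""In-memory containers for per-laboratory and cross-laboratory feature data.

A :class:`FeatureTable` holds one laboratory's feature quantification
(features x samples) together with feature metadata (m/z, retention time,
optional library annotation) and sample metadata (sample type, blank flag).
An :class:`AlignedFeatureTable` is the cross-laboratory analogue: global
consensus features x (lab, sample) columns, with a provenance map back to
each laboratory's source features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ("mz", "rt", "annotation")
SAMPLE_COLUMNS = ("sample_type", "is_blank")


def _check_matrix(intensities: pd.DataFrame) -> None:
    values = intensities.to_numpy()
    if values.size and np.nanmin(values) < 0:
        raise ValueError("intensity matrix contains negative values")
    if intensities.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    if intensities.columns.has_duplicates:
        raise ValueError("duplicate sample columns")


@dataclass
class FeatureTable:
    """One laboratory's features x samples intensity matrix with metadata.

    Parameters
    ----------
    intensities
        Non-negative matrix, rows indexed by feature id, columns by sample id.
    features
        Per-feature metadata indexed like ``intensities``; must carry ``mz``
        (Da), ``rt`` (minutes) and ``annotation`` (library ID string or NaN).
        A ``compound`` column with ground-truth provenance is optional.
    samples
        Per-sample metadata indexed by sample id with ``sample_type`` and
        boolean ``is_blank``.
    lab_id
        Laboratory token, or None for lab-agnostic tables.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    lab_id: str | None = None

    def __post_init__(self) -> None:
        _check_matrix(self.intensities)
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata index does not match intensity rows")
        if not self.samples.index.equals(self.intensities.columns):
            raise ValueError("sample metadata index does not match intensity columns")
        for col in FEATURE_COLUMNS:
            if col not in self.features.columns:
                raise ValueError(f"feature metadata missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    # -- convenience views ------------------------------------------------
    @property
    def blank_columns(self) -> list:
        return list(self.samples.index[self.samples["is_blank"].astype(bool)])

    @property
    def sample_columns(self) -> list:
        return list(self.samples.index[~self.samples["is_blank"].astype(bool)])

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), self.samples.copy(), self.lab_id
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[feature_ids],
            self.features.loc[feature_ids],
            self.samples.copy(),
            self.lab_id,
        )


@dataclass
class AlignedFeatureTable:
    """Global consensus features x (lab, sample) matrix.

    ``intensities`` columns are a two-level MultiIndex (lab, sample); a value
    of 0 means the source laboratory did not report the feature in that
    sample.  ``provenance`` maps each global feature id to the list of
    ``(lab, source_feature_id)`` pairs that were merged into it.  ``mode``
    records how the consensus space was built: ``"mz_rt"`` (MS1 m/z plus
    retention time) or ``"spectral"`` (MS/MS cosine clustering; consensus RT
    is NaN).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    mode: str = "mz_rt"

    def __post_init__(self) -> None:
        _check_matrix(self.intensities)
        if self.intensities.columns.nlevels != 2:
            raise ValueError("aligned columns must be a (lab, sample) MultiIndex")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata index does not match intensity rows")
        if not self.samples.index.equals(self.intensities.columns):
            raise ValueError("sample metadata index does not match intensity columns")
        if self.mode not in ("mz_rt", "spectral"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")

    @property
    def labs(self) -> list:
        return list(dict.fromkeys(self.intensities.columns.get_level_values(0)))

    @property
    def blank_columns(self) -> list:
        return list(self.samples.index[self.samples["is_blank"].astype(bool)])

    @property
    def sample_columns(self) -> list:
        return list(self.samples.index[~self.samples["is_blank"].astype(bool)])

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "AlignedFeatureTable":
        return AlignedFeatureTable(
            self.intensities.copy(),
            self.features.copy(),
            self.samples.copy(),
            {k: list(v) for k, v in self.provenance.items()},
            self.mode,
        )

    def subset_features(self, feature_ids) -> "AlignedFeatureTable":
        ids = list(feature_ids)
        return AlignedFeatureTable(
            self.intensities.loc[ids],
            self.features.loc[ids],
            self.samples.copy(),
            {k: list(self.provenance.get(k, [])) for k in ids},
            self.mode,
        )

    def presence_by_lab(self, include_blanks: bool = False) -> pd.DataFrame:
        """Boolean labs x features matrix: feature nonzero in >=1 sample of the lab."""
        cols = self.intensities.columns
        if not include_blanks:
            keep = ~self.samples["is_blank"].astype(bool).to_numpy()
            cols = cols[keep]
        sub = self.intensities[cols]
        present = sub.T.groupby(level=0).max() > 0
        return present  # labs x features
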