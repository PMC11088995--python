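"""Features x samples abundance container for the TPM and LFQ layers.

A thin wrapper over a pandas DataFrame that enforces the layer contract:
the transcript layer (TPM, transcripts per kilobase million) is fully
observed and non-negative; the protein layer (LFQ, label-free
quantification intensity) admits missing values (left-censored: low
intensities fall below detection) and carries a per-protein peptide
count used by the quantifiability gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CohortDesign

LAYERS = ("TPM", "LFQ")


class LayerError(ValueError):
    """Raised when an operation receives the wrong matrix layer."""


class ConsistencyError(ValueError):
    """Raised when matrix and design sample sets disagree."""


@dataclass
class ExpressionMatrix:
    """Abundance matrix with layer semantics.

    Parameters
    ----------
    values
        DataFrame, features in rows, samples in columns. NaN marks a
        missing (non-detected) value; only legal on the LFQ layer.
    layer
        ``"TPM"`` or ``"LFQ"``.
    peptide_counts
        Per-feature peptide count (LFQ layer only), aligned to
        ``values.index``.
    """

    values: pd.DataFrame = field(repr=False)
    layer: str = "TPM"
    peptide_counts: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise LayerError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            raise ConsistencyError("duplicate feature ids")
        if self.layer == "TPM":
            if self.values.isna().any().any():
                raise LayerError("TPM layer must not contain missing values")
            if (self.values.to_numpy() < 0).any():
                raise LayerError("TPM values must be non-negative")
        else:
            if self.peptide_counts is None:
                raise LayerError("LFQ layer requires peptide_counts")
            self.peptide_counts = self.peptide_counts.reindex(self.values.index)
            if self.peptide_counts.isna().any():
                raise LayerError("peptide_counts missing for some LFQ features")
            if (self.peptide_counts < 1).any():
                raise LayerError("peptide_counts must be >= 1")
            observed = self.values.to_numpy()
            if np.nanmin(observed, initial=np.inf) < 0:
                raise LayerError("LFQ intensities must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_design(self, design: CohortDesign) -> None:
        """Require sample columns to match the design exactly, in order."""
        if self.sample_ids != design.sample_ids:
            raise ConsistencyError(
                "matrix samples do not match the cohort design "
                f"({len(self.sample_ids)} columns vs {design.n_samples} samples)"
            )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        """Row subset preserving layer metadata."""
        vals = self.values.loc[list(feature_ids)]
        pep = None
        if self.peptide_counts is not None:
            pep = self.peptide_counts.loc[list(feature_ids)]
        return ExpressionMatrix(vals, layer=self.layer, peptide_counts=pep)

    def valid_mask(self) -> pd.DataFrame:
        """Boolean grid of valid values.

        A TPM value counts as valid when strictly positive (a zero TPM
        means the transcript was not observed); an LFQ value counts as
        valid when non-missing.
        """
        if self.layer == "TPM":
            return self.values > 0
        return self.values.notna()
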