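"""Filtering, imputation, quantifiability and fold-change gates.

These are the matrix-level gates applied before any feature is allowed
into the correlation screen:

* transcripts must vary at all across samples (SD > 0);
* a feature must be validly quantified in strictly more than 70% of a
  sex stratum (13 of 18 at the default design) — a zero TPM or a
  missing LFQ intensity does not count;
* proteins must be identified by >= 2 peptides and fully observed in at
  least one of the two contrasted condition cells;
* the deficient-vs-treated abundance ratio must exceed two-fold in
  either direction;
* missing LFQ intensities, when imputation is requested, are replaced
  by a low percentile (default the 1st) of the observed values of the
  same feature within the same sex x group condition — a left-censored
  noise floor, not an estimate of the true value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUPS, SEXES, CohortDesign
from .matrices import ExpressionMatrix, LayerError

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    """Raised when a feature has no observed value in some condition."""


@dataclass
class GateReport:
    """Per-feature gate flags for one stratum."""

    stratum: str
    table: pd.DataFrame = field(repr=False)  # indexed by feature id

    def passing(self, column: str) -> list[str]:
        return list(self.table.index[self.table[column]])


def tpm_variance_filter(m: ExpressionMatrix) -> list[str]:
    """Features whose across-sample standard deviation is > 0.

    A transcript reported at the same TPM in every sample carries no
    rank information and is dropped before screening.
    """
    if m.layer != "TPM":
        raise LayerError("variance filter applies to the TPM layer")
    sd = m.values.std(axis=1, ddof=1)
    return list(m.values.index[sd > 0])


def min_valid_count(n_samples: int, fraction: float = 0.70) -> int:
    """Smallest k with k / n_samples strictly greater than ``fraction``.

    ``min_valid_count(18, 0.70) == 13``: thirteen valid values among
    eighteen samples is the first count strictly above 70%.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    # floor(f*n) + 1 is the first integer strictly above f*n, whether or
    # not f*n is itself an integer; fraction < 1 keeps it <= n
    return math.floor(fraction * n_samples) + 1


def validity_filter(
    m: ExpressionMatrix,
    design: CohortDesign,
    stratum: str,
    fraction: float = 0.70,
) -> GateReport:
    """Flag features validly quantified in > ``fraction`` of a sex stratum.

    Valid means strictly positive for TPM and non-missing for LFQ.
    """
    m.check_design(design)
    ids = design.stratum_ids(stratum)  # raises on unknown stratum
    valid = m.valid_mask()[ids]
    n_valid = valid.sum(axis=1)
    threshold = min_valid_count(len(ids), fraction)
    table = pd.DataFrame(
        {"n_valid": n_valid, "validity_pass": n_valid >= threshold},
        index=m.values.index,
    )
    return GateReport(stratum=stratum, table=table)


def lfq_impute(
    m: ExpressionMatrix,
    design: CohortDesign,
    percentile: float = 1.0,
    condition: str = "sex_group",
    on_empty: str = "error",
) -> ExpressionMatrix:
    """Replace missing LFQ values by a per-condition low percentile.

    For each feature and each condition (sex x group cell by default;
    ``condition="group"`` pools sexes), missing entries are set to the
    ``percentile``-th percentile (linear interpolation between order
    statistics) of the feature's observed values in that condition.
    Observed entries are untouched. A feature with no observed value in
    a condition that needs imputing cannot be imputed per-condition;
    by default this raises :class:`ImputationError` naming the feature
    and condition, while ``on_empty="feature_floor"`` falls back to the
    same percentile of the feature's observed values across all
    samples (a left-censored cell is then filled at the feature's
    global noise floor; features observed nowhere stay missing).
    """
    if on_empty not in ("error", "feature_floor"):
        raise ValueError("on_empty must be 'error' or 'feature_floor'")
    if m.layer != "LFQ":
        raise LayerError("imputation applies to the LFQ layer")
    m.check_design(design)
    if condition == "sex_group":
        blocks = [
            (f"{sex}/{group}", design.cell_ids(sex, group))
            for sex in SEXES
            for group in GROUPS
        ]
    elif condition == "group":
        blocks = [
            (group, [s for sex in SEXES for s in design.cell_ids(sex, group)])
            for group in GROUPS
        ]
    else:
        raise ValueError("condition must be 'sex_group' or 'group'")

    out = m.values.copy()
    for label, ids in blocks:
        block = out[ids]
        missing = block.isna()
        needs = missing.any(axis=1)
        if not needs.any():
            continue
        observed_counts = block.notna().sum(axis=1)
        dead = needs & (observed_counts == 0)
        if dead.any():
            if on_empty == "error":
                feature = dead.idxmax()
                raise ImputationError(
                    f"feature {feature!r} has no observed value in condition "
                    f"{label!r}; the {percentile}%-percentile noise floor is undefined"
                )
            global_floor = m.values.quantile(
                percentile / 100.0, axis=1, interpolation="linear"
            )
            floor = block.quantile(percentile / 100.0, axis=1, interpolation="linear")
            floor = floor.where(~dead, global_floor)
        else:
            floor = block.quantile(percentile / 100.0, axis=1, interpolation="linear")
        filled = block.where(~missing, floor, axis=0)
        out[ids] = filled
    return ExpressionMatrix(out, layer="LFQ", peptide_counts=m.peptide_counts)


def quantifiability_mask(
    m: ExpressionMatrix,
    design: CohortDesign,
    condition_pair: tuple[str, str] = ("GL40", "GL00"),
    stratum: str | None = None,
) -> list[str]:
    """Proteins quantifiable for the two-condition contrast.

    Keeps features identified by >= 2 peptides AND fully observed
    (>= 3 intensities) in at least one of the two contrasted cells.
    With ``stratum`` the cells are (sex, group); without, replicates of
    both sexes in each group are pooled and >= 3 observed are required
    in one group.
    """
    if m.layer != "LFQ":
        raise LayerError("quantifiability applies to the LFQ layer")
    m.check_design(design)
    for group in condition_pair:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
    sexes = [stratum] if stratum is not None else list(SEXES)
    observed = m.values.notna()
    ok_cells = []
    for group in condition_pair:
        if stratum is not None:
            ids = design.cell_ids(stratum, group)
            ok_cells.append(observed[ids].sum(axis=1) >= 3)
        else:
            ids = [s for sex in sexes for s in design.cell_ids(sex, group)]
            ok_cells.append(observed[ids].sum(axis=1) >= 3)
    cell_ok = np.logical_or.reduce(ok_cells)
    pep_ok = m.peptide_counts >= 2
    keep = pd.Series(cell_ok, index=m.values.index) & pep_ok
    return list(m.values.index[keep])


def group_fold_change(
    m: ExpressionMatrix,
    design: CohortDesign,
    stratum: str,
    numerator: str = "GL40",
    denominator: str = "GL00",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-feature mean abundance ratio between two groups in one stratum.

    The ratio is taken on the abundance scale (mean of numerator cell /
    mean of denominator cell, missing values ignored); ``fold_pass`` is
    true when the change exceeds ``threshold``-fold in either direction
    (max(r, 1/r) > threshold), so both induced and repressed features
    pass the same gate. A zero or fully-missing denominator leaves the
    ratio undefined (NaN) and fails the gate with a logged warning.
    """
    m.check_design(design)
    num_ids = design.cell_ids(stratum, numerator)
    den_ids = design.cell_ids(stratum, denominator)
    num_mean = m.values[num_ids].mean(axis=1)
    den_mean = m.values[den_ids].mean(axis=1)

    ratio = pd.Series(np.nan, index=m.values.index)
    ok = (den_mean > 0) & num_mean.notna()
    ratio[ok] = num_mean[ok] / den_mean[ok]
    bad = (~ok) & (num_mean.notna() | den_mean.notna())
    if bad.any():
        logger.warning(
            "%d features with zero or unobserved %s mean: ratio undefined",
            int(bad.sum()), denominator,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        either_way = np.maximum(ratio, 1.0 / ratio)
    fold_pass = pd.Series(either_way > threshold, index=ratio.index).fillna(False)
    return pd.DataFrame({"ratio": ratio, "fold_pass": fold_pass})
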