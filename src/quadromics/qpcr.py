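"""Relative quantification of qPCR Ct tables by the delta-Ct method.

A Ct (quantification cycle) is the PCR cycle at which a target's
fluorescence crosses threshold; each cycle is a doubling, so abundance
is 2^(-Ct) up to a plate constant. The delta-Ct method cancels the
plate constant against reference genes measured in the same sample:

    dCt    = Ct(target) - mean Ct(references)
    RQ     = 2^(-dCt),  rescaled so the control-group mean is 1.

Total-RNA assays normalise against stable housekeeping genes (Atp5o,
Ubc by default); polysome-fraction assays normalise against 18S rRNA,
which is what the ``reference_genes`` argument carries in that case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .polysome import welch_compare  # noqa: F401  (re-export: the follow-up test)

REQUIRED_COLUMNS = ("sample_id", "group", "fraction", "gene", "ct")


class NormalizationError(ValueError):
    """Raised when a sample lacks the reference genes needed to normalise."""


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def delta_ct_relative_quantity(
    table: pd.DataFrame,
    gene: str,
    reference_genes,
    control_group: str = "GL00",
    fraction: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample relative quantities of ``gene`` and a group summary.

    Parameters
    ----------
    table
        Long-format Ct table with columns
        ``sample_id, group, fraction, gene, ct``.
    reference_genes
        Genes whose arithmetic-mean Ct normalises each (sample,
        fraction); equivalent to the geometric mean of their quantities.
    control_group
        Group whose mean relative quantity is rescaled to 1 (per
        fraction).
    fraction
        Restrict to one fraction label; default uses all fractions
        present for ``gene``.

    Returns
    -------
    (per_sample, summary)
        Per-sample rows ``sample_id, group, fraction, delta_ct,
        relative_quantity``; summary has group x fraction mean, sd, n.
    """
    _check_table(table)
    reference_genes = list(reference_genes)
    sub = table[table["gene"] == gene]
    if fraction is not None:
        sub = sub[sub["fraction"] == fraction]
    if sub.empty:
        raise ValueError(f"no Ct rows for gene {gene!r}")

    refs = table[table["gene"].isin(reference_genes)]
    ref_ct = refs.groupby(["sample_id", "fraction"])["ct"].agg(["mean", "size"])

    rows = []
    for _, row in sub.iterrows():
        key = (row["sample_id"], row["fraction"])
        if key not in ref_ct.index or ref_ct.loc[key, "size"] < len(reference_genes):
            raise NormalizationError(
                f"sample {row['sample_id']!r} fraction {row['fraction']!r} "
                f"lacks reference genes {reference_genes}"
            )
        dct = row["ct"] - ref_ct.loc[key, "mean"]
        rows.append(
            {
                "sample_id": row["sample_id"],
                "group": row["group"],
                "fraction": row["fraction"],
                "delta_ct": float(dct),
                "relative_quantity": float(2.0 ** (-dct)),
            }
        )
    per_sample = pd.DataFrame(rows)

    # rescale so the control-group mean is 1 within each fraction
    for frac, block in per_sample.groupby("fraction"):
        ctrl = block.loc[block["group"] == control_group, "relative_quantity"]
        if len(ctrl) and ctrl.mean() > 0:
            per_sample.loc[block.index, "relative_quantity"] /= ctrl.mean()

    summary = (
        per_sample.groupby(["group", "fraction"])["relative_quantity"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return per_sample, summary
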