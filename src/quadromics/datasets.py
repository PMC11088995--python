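"""Packaged reference tables.

``load_common_correlates`` returns the 23 liver proteins whose LFQ
intensity correlated with hepatic ascorbate in both sexes of a
36-mouse dose-ladder cohort (18 positively — dominated by mitochondrial
complex III subunits and iron-storage proteins — and 5 negatively,
including acute-phase/complement proteins), with the per-sex Spearman
rho values. Useful as a known-answer input for the cross-sex overlap
and sign-classification steps.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_common_correlates() -> pd.DataFrame:
    """23 proteins x (rho_female, rho_male), indexed by gene symbol."""
    ref = resources.files("quadromics").joinpath("data/common_correlates.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="symbol")
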