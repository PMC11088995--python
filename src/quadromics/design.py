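"""Cohort layout: six treatment groups x two sexes x replicates.

The study design encoded here is a dose-ladder of ascorbate (vitamin C)
supplementation in Gulo-null mice, which cannot synthesise their own
ascorbate, plus a rescue arm and a wild-type reference:

========  =====================================================
group     treatment
========  =====================================================
GL00      Gulo-null, ascorbate withdrawn for the final month
GL01      Gulo-null, 0.01% ascorbate in drinking water
GL05      Gulo-null, 0.05% ascorbate
GL40      Gulo-null, 0.4% ascorbate since weaning
GLR40     Gulo-null, depletion then 0.4% re-supplementation
WT00      wild type, no supplementation (endogenous synthesis)
========  =====================================================

Every (sex, group) cell carries at least three biological replicates;
the default design of 3 per cell gives 36 animals, i.e. 18 per sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SEXES: tuple[str, ...] = ("F", "M")
GROUPS: tuple[str, ...] = ("GL00", "GL01", "GL05", "GL40", "GLR40", "WT00")

#: groups compared by the two-fold abundance gate (deficient vs fully treated)
FOLD_GATE_GROUPS: tuple[str, str] = ("GL40", "GL00")

MIN_REPLICATES = 3


class InvalidDesignError(ValueError):
    """Raised when a cohort layout violates the minimum-replication design."""


@dataclass(frozen=True)
class CohortDesign:
    """Sample -> (sex, group, replicate) map for a paired-omics cohort.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``sex``, ``group``,
        ``replicate``, one row per animal, in matrix column order.
    """

    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "group", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise InvalidDesignError(f"design table missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            dupes = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise InvalidDesignError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise InvalidDesignError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_grp = set(self.samples["group"]) - set(GROUPS)
        if bad_grp:
            raise InvalidDesignError(f"unknown group labels: {sorted(bad_grp)}")
        cell_sizes = self.samples.groupby(["sex", "group"], observed=True).size()
        if len(cell_sizes) != len(SEXES) * len(GROUPS):
            raise InvalidDesignError("every (sex, group) cell must be populated")
        if (cell_sizes < MIN_REPLICATES).any():
            small = cell_sizes[cell_sizes < MIN_REPLICATES]
            raise InvalidDesignError(
                f"cells below the {MIN_REPLICATES}-replicate minimum: "
                f"{list(small.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sex_of(self) -> pd.Series:
        """Sex label per sample, indexed by sample_id."""
        return self.samples.set_index("sample_id")["sex"]

    def group_of(self) -> pd.Series:
        """Group label per sample, indexed by sample_id."""
        return self.samples.set_index("sample_id")["group"]

    def stratum_ids(self, sex: str) -> list[str]:
        """Sample ids of one sex, in design order."""
        if sex not in SEXES:
            raise InvalidDesignError(f"unknown stratum {sex!r}; expected one of {SEXES}")
        mask = self.samples["sex"] == sex
        return list(self.samples.loc[mask, "sample_id"])

    def cell_ids(self, sex: str, group: str) -> list[str]:
        """Sample ids of one (sex, group) cell, in design order."""
        if sex not in SEXES:
            raise InvalidDesignError(f"unknown sex {sex!r}")
        if group not in GROUPS:
            raise InvalidDesignError(f"unknown group {group!r}")
        mask = (self.samples["sex"] == sex) & (self.samples["group"] == group)
        return list(self.samples.loc[mask, "sample_id"])


def generate_cohort(n_per_cell: int = 3, seed: int = 0) -> CohortDesign:
    """Build the standard 6-group x 2-sex cohort layout.

    Sample ids are deterministic given ``seed`` (the seed is recorded in
    the id prefix so matrices simulated from different seeds cannot be
    silently mixed; the layout itself does not depend on it).

    Parameters
    ----------
    n_per_cell
        Biological replicates per (sex, group) cell; must be >= 3, the
        design minimum.
    seed
        Cohort label seed, embedded in sample ids.

    Returns
    -------
    CohortDesign
        ``2 * 6 * n_per_cell`` samples; 36 for the default ``n_per_cell=3``.
    """
    if n_per_cell < MIN_REPLICATES:
        raise InvalidDesignError(
            f"n_per_cell={n_per_cell} is below the design minimum of "
            f"{MIN_REPLICATES} replicates per (sex, group) cell"
        )
    rows = [
        {
            "sample_id": f"c{seed}_{sex}{group}_r{rep}",
            "sex": sex,
            "group": group,
            "replicate": rep,
        }
        for sex in SEXES
        for group in GROUPS
        for rep in range(1, n_per_cell + 1)
    ]
    return CohortDesign(pd.DataFrame(rows))
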