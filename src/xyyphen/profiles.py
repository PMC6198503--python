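"""Reference-normalized phenotype profiles and diagnostic-subgroup contrasts.

Scores are Z-normalized against a declared reference population — the
instrument's population norms, or an external ASD comparison sample (an
SSC-like all-male cohort) — optionally after restricting the cohort by age
(strictly younger than a cutoff, default 18 years, to match the reference's
age coverage).  Diagnostic subgroups (DSM-5 ASD, community-diagnosis-only,
no ASD) are then contrasted variable-by-variable through the same
normality gate used for the cohort descriptives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .descriptives import DegenerateInputError, gated_group_contrast

__all__ = [
    "ReferenceNorms",
    "z_normalize",
    "invert_z",
    "restrict_by_age",
    "diagnostic_subgroups",
    "subgroup_profile_contrasts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceNorms:
    """Per-variable reference mean/SD (long table: variable, ref_mean,
    ref_sd, plus population label / size / age range metadata)."""

    table: pd.DataFrame
    population: str = "reference"

    def __post_init__(self) -> None:
        required = {"variable", "ref_mean", "ref_sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"norms table lacks columns: {sorted(missing)}")
        if self.table["variable"].duplicated().any():
            raise ValueError("duplicate variables in norms table")
        if (self.table["ref_sd"] <= 0).any():
            bad = self.table.loc[self.table["ref_sd"] <= 0, "variable"].tolist()
            raise ValueError(f"non-positive reference SD for: {bad}")

    @property
    def variables(self) -> list[str]:
        return list(self.table["variable"])

    def lookup(self) -> tuple[pd.Series, pd.Series]:
        t = self.table.set_index("variable")
        return t["ref_mean"], t["ref_sd"]

    @classmethod
    def from_population_norms(cls, dictionary: pd.DataFrame) -> "ReferenceNorms":
        """Norms from a data dictionary's instrument population columns
        (variables without population norms are omitted)."""
        t = dictionary.dropna(subset=["pop_norm_mean", "pop_norm_sd"])
        return cls(
            pd.DataFrame(
                {
                    "variable": t["variable"].to_numpy(),
                    "ref_mean": t["pop_norm_mean"].to_numpy(dtype=float),
                    "ref_sd": t["pop_norm_sd"].to_numpy(dtype=float),
                }
            ),
            population="instrument population norms",
        )


def z_normalize(
    data: pd.DataFrame,
    norms: ReferenceNorms,
    variables: list[str] | None = None,
    direction: dict[str, bool] | None = None,
    harmonize_direction: bool = False,
) -> pd.DataFrame:
    """Z = (score - ref_mean) / ref_sd per variable; missing propagates.

    ``variables`` defaults to every normed variable present in ``data``;
    requesting a variable without norms raises, listing the offenders.
    With ``harmonize_direction`` and a ``direction`` map (variable ->
    higher-is-worse flag), higher-is-worse variables are sign-flipped so
    impairment points the same way across the profile.
    """
    ref_mean, ref_sd = norms.lookup()
    if variables is None:
        variables = [v for v in norms.variables if v in data.columns]
    uncovered = [v for v in variables if v not in ref_mean.index]
    if uncovered:
        raise KeyError(f"variables lacking reference norms: {uncovered}")
    absent = [v for v in variables if v not in data.columns]
    if absent:
        raise KeyError(f"variables absent from the table: {absent}")
    z = (data[variables] - ref_mean[variables]) / ref_sd[variables]
    if harmonize_direction:
        if direction is None:
            raise ValueError("harmonize_direction requires a direction map")
        for v in variables:
            if direction.get(v, False):
                z[v] = -z[v]
    return z


def invert_z(z: pd.DataFrame, norms: ReferenceNorms) -> pd.DataFrame:
    """Algebraic inverse of :func:`z_normalize` (raw Z, unharmonized)."""
    ref_mean, ref_sd = norms.lookup()
    cols = list(z.columns)
    return z * ref_sd[cols] + ref_mean[cols]


def restrict_by_age(
    data: pd.DataFrame, max_age: float = 18.0, age_col: str = "age_years"
) -> pd.DataFrame:
    """Participants strictly younger than ``max_age`` (exactly ``max_age``
    is excluded).  Idempotent; warns when nobody qualifies."""
    if age_col not in data.columns:
        raise KeyError(f"no age column {age_col!r}")
    subset = data[data[age_col] < max_age]
    log.info("age restriction < %s: kept %d of %d", max_age, len(subset), len(data))
    if subset.empty:
        warnings.warn(f"no participants younger than {max_age}", stacklevel=2)
    return subset


def diagnostic_subgroups(data: pd.DataFrame,
                         dsm5_col: str = "dsm5_asd",
                         community_col: str = "community_asd") -> pd.Series:
    """Three-way diagnostic status: ``dsm5_asd`` (research criteria met),
    ``community_only`` (community diagnosis not confirmed), ``no_asd``."""
    dsm5 = data[dsm5_col] == 1
    comm = data[community_col] == 1
    out = pd.Series(np.where(dsm5, "dsm5_asd", np.where(comm, "community_only", "no_asd")),
                    index=data.index, name="subgroup")
    return out


def subgroup_profile_contrasts(
    z: pd.DataFrame,
    subgroups: pd.Series,
    min_group_n: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise subgroup contrasts for every profile variable.

    Each contrast runs through the normality gate (t test vs Wilcoxon).
    Output is long-format: one row per (variable, pair), with the method
    chosen, statistic, p, group sizes — or a skip reason when a subgroup is
    too small or the variable degenerate.
    """
    labels = [g for g in pd.unique(subgroups.dropna()) if (subgroups == g).sum() > 0]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty subgroups")
    rows = []
    for var in z.columns:
        for ga, gb in combinations(labels, 2):
            xa = z.loc[subgroups == ga, var].dropna()
            xb = z.loc[subgroups == gb, var].dropna()
            row = {"variable": var, "group_a": ga, "group_b": gb,
                   "n_a": len(xa), "n_b": len(xb)}
            if len(xa) < min_group_n or len(xb) < min_group_n:
                row.update(method="skipped", statistic=np.nan, p=np.nan,
                           note=f"subgroup below n={min_group_n}")
            else:
                try:
                    res, summ = gated_group_contrast(xa, xb, alpha=alpha)
                    row.update(method=res.method, statistic=res.statistic, p=res.p,
                               note="normal" if summ.is_normal else "non-normal")
                except DegenerateInputError as err:
                    row.update(method="skipped", statistic=np.nan, p=np.nan, note=str(err))
            rows.append(row)
    return pd.DataFrame(rows)
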