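"""Progeny female-ratio computation and condition comparison.

The female ratio of a brood is females / (females + hermaphrodites) —
males are excluded by definition.  Condition aggregates are computed from
mean counts (mean females / (mean females + mean hermaphrodites)), not as
the mean of per-mother ratios; both are reported because they differ when
brood sizes vary.  Conditions are compared with the exact Mann-Whitney U
test on per-mother ratios.

A packaged fixture table (``auanema/data/rnai_progeny.tsv``) carries the
17-mother dmd-10/11 RNAi experiment for the worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from auanema.io import ProgenyTable, read_progeny
from auanema.stats import TestResult, mann_whitney_u

__all__ = [
    "RatioReport",
    "female_ratio",
    "compare_conditions",
    "load_rnai_fixture",
]


@dataclass(frozen=True)
class RatioReport:
    """Per-mother ratios, per-condition aggregates and the U test."""

    per_mother: pd.DataFrame  # mother_id, condition, female_ratio
    aggregate: dict[str, float]  # condition -> meanF/(meanF+meanH)
    mean_of_ratios: dict[str, float]
    test: TestResult


def female_ratio(females: int, hermaphrodites: int) -> float:
    """females / (females + hermaphrodites)."""
    if females < 0 or hermaphrodites < 0:
        raise ValueError("counts must be nonnegative")
    denom = females + hermaphrodites
    if denom == 0:
        raise ValueError("zero females + hermaphrodites")
    return females / denom


def compare_conditions(pt: ProgenyTable) -> RatioReport:
    """Compare female ratios between the RNAi and Control conditions.

    The test is ``mann_whitney_u(RNAi ratios, Control ratios)`` in exact
    mode; the report is invariant to row order.
    """
    df = pt.rows
    conditions = set(df["condition"])
    for needed in ("RNAi", "Control"):
        if needed not in conditions or not len(df[df["condition"] == needed]):
            raise ValueError(f"condition {needed!r} has no mothers")
    per_mother = df.assign(
        female_ratio=[
            female_ratio(f, h)
            for f, h in zip(df["females"], df["hermaphrodites"])
        ]
    )[["mother_id", "condition", "female_ratio"]]
    aggregate = {}
    mean_of_ratios = {}
    for cond, sub in df.groupby("condition"):
        mean_f = sub["females"].mean()
        mean_h = sub["hermaphrodites"].mean()
        aggregate[cond] = mean_f / (mean_f + mean_h)
        mean_of_ratios[cond] = float(
            per_mother.loc[per_mother["condition"] == cond, "female_ratio"].mean()
        )
    ratios = {
        cond: per_mother.loc[
            per_mother["condition"] == cond, "female_ratio"
        ].to_numpy()
        for cond in ("RNAi", "Control")
    }
    test = mann_whitney_u(ratios["RNAi"], ratios["Control"], mode="exact")
    return RatioReport(per_mother.reset_index(drop=True), aggregate,
                       mean_of_ratios, test)


def load_rnai_fixture() -> ProgenyTable:
    """The packaged 17-mother dmd-10/11 RNAi progeny table."""
    ref = resources.files("auanema").joinpath("data/rnai_progeny.tsv")
    with resources.as_file(ref) as path:
        return read_progeny(Path(path))
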