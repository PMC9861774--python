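"""Stratified 40/40/20 training / validation / test partition.

Patients are stratified jointly by cohort of origin and outcome status, so
each set preserves both the cohort proportions and the EDA/NEDA ratio.
Within each stratum the three target counts come from largest-remainder
rounding; strata are processed from largest to smallest and remainder ties
are given to the set with the smallest running total (then by set order),
which keeps the global set sizes as close to the exact fractions as the
stratum structure allows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SET_NAMES = ("TRset", "Vset", "TEset")
DEFAULT_FRACTIONS = (0.4, 0.4, 0.2)


@dataclass
class SplitAssignment:
    """Patient-to-set assignment plus the strata it was computed on."""

    assignment: pd.Series  # patient_id -> set name
    strata: pd.Series  # patient_id -> (cohort, status) label
    seed: int

    def ids(self, set_name: str) -> list:
        if set_name not in SET_NAMES:
            raise ValueError(f"unknown set {set_name!r}")
        return self.assignment.index[self.assignment == set_name].tolist()

    @property
    def sizes(self) -> dict:
        return {name: int((self.assignment == name).sum()) for name in SET_NAMES}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.assignment.index,
                "set": self.assignment.to_numpy(),
                "stratum": self.strata.loc[self.assignment.index].to_numpy(),
            }
        )


def stratum_allocation(
    stratum_sizes: dict, fractions=DEFAULT_FRACTIONS
) -> dict:
    """Largest-remainder set counts per stratum.

    ``stratum_sizes`` maps stratum key -> patient count.  Strata are
    processed from largest to smallest (ties by key); remainder ties within a
    stratum go to the set with the smallest running global total, then by
    set order.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    totals = np.zeros(len(fractions))
    allocation = {}
    order = sorted(stratum_sizes, key=lambda k: (-stratum_sizes[k], str(k)))
    for key in order:
        n = int(stratum_sizes[key])
        exact = np.array([f * n for f in fractions])
        base = np.floor(exact + 1e-9).astype(int)
        remainders = exact - base
        totals += base
        counts = base.copy()
        for _ in range(n - int(base.sum())):
            # highest remainder first; ties to the most under-filled set
            ranked = sorted(
                range(len(fractions)),
                key=lambda i: (-round(remainders[i], 9), totals[i], i),
            )
            i = ranked[0]
            counts[i] += 1
            totals[i] += 1
            remainders[i] = -1.0
        allocation[key] = counts
    return allocation


def stratified_split(
    labels: pd.Series,
    cohorts: pd.Series,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign every patient to TRset / Vset / TEset.

    ``labels`` maps patient_id -> outcome status ("EDA"/"NEDA"), ``cohorts``
    maps patient_id -> cohort name.  Within each (cohort, status) stratum,
    membership is random given ``seed`` but the per-stratum set counts are
    deterministic (largest remainder).  The result is independent of the
    input ordering.
    """
    labels = pd.Series(labels)
    cohorts = pd.Series(cohorts)
    missing = labels.index.difference(cohorts.index)
    if len(missing):
        raise ValueError(f"patients without cohort: {list(missing[:5])}")
    strata = pd.Series(
        list(zip(cohorts.loc[labels.index], labels)), index=labels.index
    )
    sizes = strata.value_counts().to_dict()
    allocation = stratum_allocation(sizes, fractions)

    assignment = pd.Series(index=labels.index, dtype=object)
    stratum_keys = sorted(sizes, key=lambda k: (-sizes[k], str(k)))
    for rank, key in enumerate(stratum_keys):
        members = sorted(strata.index[strata == key])
        rng = np.random.default_rng(np.random.SeedSequence([seed, rank]))
        members = list(np.array(members, dtype=object)[rng.permutation(len(members))])
        counts = allocation[key]
        start = 0
        for set_name, c in zip(SET_NAMES, counts):
            assignment.loc[members[start : start + c]] = set_name
            start += c
    return SplitAssignment(assignment=assignment, strata=strata, seed=seed)
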