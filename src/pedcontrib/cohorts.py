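"""Case/control birth cohorts and per-cohort descriptive statistics.

Cohorts are overlapping birth-year windows (three years wide by default,
sliding by one year), one affected and one control cohort per window.
Contemporary controls are matched on birth year and sampled without
replacement, a fixed number per case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import PedigreeError
from .pedigree import (
    Pedigree,
    ancestors_of,
    average_relationship,
    completeness,
    inbreeding,
)

__all__ = [
    "Cohort",
    "CohortDescriptives",
    "build_cohorts",
    "sample_controls",
    "cohort_descriptives",
]


@dataclass(frozen=True)
class Cohort:
    """A labeled three-year birth-window subset of cases or controls."""

    group: str  # "affected" | "control"
    year_start: int
    year_end: int
    members: tuple[str, ...]

    def __post_init__(self):
        if self.group not in ("affected", "control"):
            raise ValueError(f"invalid cohort group {self.group!r}")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")

    @property
    def window_label(self) -> str:
        return f"{self.year_start % 100:02d}/{self.year_end % 100:02d}"

    @property
    def label(self) -> str:
        return ("A" if self.group == "affected" else "C") + self.window_label

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CohortDescriptives:
    """Table-2-style pedigree statistics for one cohort."""

    label: str
    cohort_size: int
    pedigree_size: int
    avg_inbreeding: float
    max_inbreeding: float
    min_inbreeding: float
    n_sires: int
    n_dams: int
    avg_relationship: float
    avg_pci: float


def _check_birth_years(ids: Iterable[str], ped: Pedigree, what: str) -> None:
    missing = sorted(a for a in ids if ped[a].birth_year is None)
    if missing:
        raise PedigreeError(f"{what} without birth_year: {missing}")


def build_cohorts(
    cases: Iterable[str],
    controls: Iterable[str],
    ped: Pedigree,
    first_year: int = 1993,
    last_year: int = 2007,
    window: int = 3,
) -> list[Cohort]:
    """Sliding birth-year windows; one affected and one control cohort each.

    Windows are inclusive on both ends and slide by one year:
    [first, first+window-1], ..., ending at last_year.  An animal with a
    birth year inside several windows belongs to each of those cohorts.
    """
    cases = sorted(set(cases))
    controls = sorted(set(controls))
    _check_birth_years(cases, ped, "case members")
    _check_birth_years(controls, ped, "control members")
    cohorts = []
    for start in range(first_year, last_year - window + 2):
        end = start + window - 1
        for group, pool in (("affected", cases), ("control", controls)):
            members = tuple(a for a in pool if start <= ped[a].birth_year <= end)
            cohorts.append(Cohort(group, start, end, members))
    return cohorts


def sample_controls(
    cases: Sequence[str],
    pool: Sequence[str],
    ped: Pedigree,
    ratio: int = 5,
    seed: int = 0,
) -> list[str]:
    """Draw birth-year-matched contemporaries, ``ratio`` per case.

    Sampling is without replacement and no control is reused across
    cases; the draw is deterministic for a given seed.
    """
    case_set = set(cases)
    if case_set & set(pool):
        raise PedigreeError("control pool overlaps the case list")
    _check_birth_years(case_set, ped, "cases")
    _check_birth_years(set(pool), ped, "control pool")
    rng = np.random.default_rng(seed)
    by_year: dict[int, list[str]] = {}
    for a in sorted(set(pool)):
        by_year.setdefault(ped[a].birth_year, []).append(a)
    chosen: list[str] = []
    for case in sorted(case_set, key=lambda a: (ped[a].birth_year, a)):
        year = ped[case].birth_year
        candidates = by_year.get(year, [])
        if len(candidates) < ratio:
            raise PedigreeError(
                f"insufficient birth-year-matched controls for case {case!r} "
                f"(year {year}: {len(candidates)} available, {ratio} needed)"
            )
        picks = rng.choice(len(candidates), size=ratio, replace=False)
        for i in sorted(picks, reverse=True):
            chosen.append(candidates.pop(i))
    return sorted(chosen)


def cohort_descriptives(cohort: Cohort, ped: Pedigree) -> CohortDescriptives:
    """Aggregate inbreeding, parent counts, relatedness and PCI for a cohort."""
    members = list(cohort.members)
    if not members:
        raise PedigreeError(f"empty cohort {cohort.label}")
    f = inbreeding(ped, members)
    sires = {ped[a].sire_id for a in members} - {None}
    dams = {ped[a].dam_id for a in members} - {None}
    rel = average_relationship(ped, members) if len(set(members)) >= 2 else float("nan")
    pcis = completeness(ped, members)
    return CohortDescriptives(
        label=cohort.label,
        cohort_size=len(members),
        pedigree_size=len(set(members) | ancestors_of(ped, members)),
        avg_inbreeding=f.average,
        max_inbreeding=f.maximum,
        min_inbreeding=f.minimum,
        n_sires=len(sires),
        n_dams=len(dams),
        avg_relationship=rel,
        avg_pci=pcis.average,
    )
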