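"""Appearance counting of ancestors in five-generation pedigrees.

An occurrence is a filled ancestor *slot* (path-distinct position) within
``depth`` generations of a case animal; the same ancestor can occupy
several slots.  An occurrence is "via sire" when the first step of its
path from the case is the sire link, "via dam" when it is the dam link.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import PedigreeError
from .pedigree import Pedigree

__all__ = ["AppearanceProfile", "appearance_counts", "build_profile"]


@dataclass(frozen=True)
class AppearanceProfile:
    """Aggregate appearance pattern of one ancestor over a case set."""

    ancestor_id: str
    depth: int
    per_case: Mapping[str, tuple[int, int]]  # case -> (via_sire, via_dam)
    n_cases: int

    @property
    def n_cases_with_ancestor(self) -> int:
        return sum(1 for s, d in self.per_case.values() if s + d >= 1)

    @property
    def n_cases_once(self) -> int:
        return sum(1 for s, d in self.per_case.values() if s + d == 1)

    @property
    def n_cases_multiple(self) -> int:
        return sum(1 for s, d in self.per_case.values() if s + d >= 2)

    @property
    def n_cases_via_sire_only(self) -> int:
        return sum(1 for s, d in self.per_case.values() if s >= 1 and d == 0)

    @property
    def n_cases_via_dam_only(self) -> int:
        return sum(1 for s, d in self.per_case.values() if d >= 1 and s == 0)

    @property
    def n_cases_via_both(self) -> int:
        return sum(1 for s, d in self.per_case.values() if s >= 1 and d >= 1)

    @property
    def pct_cases_with_ancestor(self) -> float:
        return 100.0 * self.n_cases_with_ancestor / self.n_cases


def _count_in_line(ped: Pedigree, root: str | None, ancestor: str, depth: int) -> int:
    """Slots occupied by ``ancestor`` within ``depth`` generations of one line."""
    count = 0
    stack = [(root, 1)]
    while stack:
        aid, gen = stack.pop()
        if aid is None or gen > depth:
            continue
        if aid == ancestor:
            count += 1
        rec = ped[aid]
        stack.append((rec.sire_id, gen + 1))
        stack.append((rec.dam_id, gen + 1))
    return count


def appearance_counts(
    ped: Pedigree, case_id: str, ancestor: str, depth: int = 5
) -> tuple[int, int]:
    """(via_sire, via_dam) slot counts of an ancestor in one case's pedigree."""
    if depth < 1:
        raise PedigreeError("depth must be >= 1")
    rec = ped[case_id]
    ped[ancestor]
    via_sire = _count_in_line(ped, rec.sire_id, ancestor, depth)
    via_dam = _count_in_line(ped, rec.dam_id, ancestor, depth)
    return via_sire, via_dam


def build_profile(
    ped: Pedigree, cases: Iterable[str], ancestor: str, depth: int = 5
) -> AppearanceProfile:
    """Aggregate appearance counts of one ancestor over a set of cases."""
    case_ids = sorted(set(cases))
    if not case_ids:
        raise PedigreeError("empty case set")
    per_case = {c: appearance_counts(ped, c, ancestor, depth) for c in case_ids}
    return AppearanceProfile(ancestor, depth, per_case, len(case_ids))


def profiles_table(ped: Pedigree, cases: Iterable[str], ancestors: Iterable[str], depth: int = 5):
    """One row per ancestor, Fig 3-5-style aggregates; percentages to 1 decimal."""
    import pandas as pd

    rows = []
    for anc in ancestors:
        prof = build_profile(ped, cases, anc, depth)
        rows.append(
            {
                "ancestor": anc,
                "n_cases_with_ancestor": prof.n_cases_with_ancestor,
                "once": prof.n_cases_once,
                "multiple": prof.n_cases_multiple,
                "via_sire_only": prof.n_cases_via_sire_only,
                "via_dam_only": prof.n_cases_via_dam_only,
                "via_both": prof.n_cases_via_both,
                "pct_cases": round(prof.pct_cases_with_ancestor, 1),
            }
        )
    return pd.DataFrame(rows).set_index("ancestor")
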