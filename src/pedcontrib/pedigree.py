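"""Pedigree data model, I/O and classical pedigree statistics.

The pedigree is a directed acyclic parent graph over animals.  Unknown
parents are represented as ``None`` and behave as unrelated founders in
every computation: kinship to an unknown ancestor is zero and genetic
contributions do not flow through an unknown link.

Provided here: validated construction and delimited-text I/O, topological
ordering, Wright's inbreeding coefficient F via memoized recursive kinship,
average additive relationship within a group, the five-generation pedigree
completeness index (PCI), and the pseudo-founder primitive used by the
probabilities-of-gene-origin decomposition.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CycleError, PedigreeError, UnknownAnimalError

#: Input tokens treated as an unknown parent.
UNKNOWN_TOKENS = {"", "0", "NA", "na", "nan", ".", "-"}

_SEX_ALIASES = {
    "m": "male", "male": "male", "s": "male", "stallion": "male", "1": "male",
    "f": "female", "female": "female", "mare": "female", "2": "female",
}
_GAITS = {"pacer", "trotter", "unknown"}
_ROLES = {"case", "control", "ancestor_only"}


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parents, birth year, sex and annotations."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    birth_year: int | None = None
    sex: str = "unknown"
    gait: str = "unknown"
    role: str = "ancestor_only"

    def __post_init__(self):
        if not self.animal_id:
            raise PedigreeError("empty animal_id")
        if self.animal_id == self.sire_id or self.animal_id == self.dam_id:
            raise PedigreeError(f"self-parenting: {self.animal_id!r} lists itself as a parent")
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.animal_id!r}")
        if self.gait not in _GAITS:
            raise PedigreeError(f"invalid gait {self.gait!r} for {self.animal_id!r}")
        if self.role not in _ROLES:
            raise PedigreeError(f"invalid role {self.role!r} for {self.animal_id!r}")

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class _Index:
    """Dense array view of a pedigree in topological order."""

    def __init__(self, records: Mapping[str, PedigreeRecord]):
        graph = nx.DiGraph()
        graph.add_nodes_from(records)
        for rec in records.values():
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None:
                    graph.add_edge(parent, rec.animal_id)
        if not nx.is_directed_acyclic_graph(graph):
            raise CycleError([a for a, _ in nx.find_cycle(graph)])
        # longest-path depth from founders; sorting by (level, id) is a
        # deterministic topological order (parents are strictly shallower)
        level = {}
        for aid in nx.topological_sort(graph):
            rec = records[aid]
            level[aid] = 1 + max(
                (level[p] for p in (rec.sire_id, rec.dam_id) if p is not None),
                default=-1,
            )
        self.ids: list[str] = sorted(records, key=lambda a: (level[a], a))
        self.pos: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        n = len(self.ids)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        self.level = np.empty(n, dtype=np.int64)
        self.birth_year = np.full(n, np.nan)
        for i, aid in enumerate(self.ids):
            rec = records[aid]
            if rec.sire_id is not None:
                self.sire[i] = self.pos[rec.sire_id]
            if rec.dam_id is not None:
                self.dam[i] = self.pos[rec.dam_id]
            self.level[i] = level[aid]
            if rec.birth_year is not None:
                self.birth_year[i] = rec.birth_year
        order = np.arange(n)
        self.level_groups: list[np.ndarray] = [
            order[self.level == lv] for lv in range(int(self.level.max(initial=0)) + 1)
        ]


class Pedigree(Mapping):
    """Immutable, validated collection of :class:`PedigreeRecord`.

    Mapping interface: ``ped[animal_id]`` returns the record, iteration
    yields animal ids.  All derived structure (topological order, kinship
    memo) is cached on first use.
    """

    def __init__(self, records: Iterable[PedigreeRecord], permissive_parents: bool = False):
        recs: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.animal_id in recs:
                raise PedigreeError(f"duplicate animal_id {rec.animal_id!r}")
            recs[rec.animal_id] = rec
        dangling = []
        for rec in list(recs.values()):
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in recs:
                    dangling.append(parent)
        if dangling:
            if permissive_parents:
                for parent in dangling:
                    recs.setdefault(parent, PedigreeRecord(animal_id=parent))
            else:
                raise PedigreeError(
                    f"parent ids without a record: {sorted(set(dangling))!r} "
                    "(pass permissive_parents=True to auto-create founder records)"
                )
        for rec in recs.values():
            sire = recs.get(rec.sire_id) if rec.sire_id else None
            if sire is not None and sire.sex == "female":
                raise PedigreeError(f"sire {sire.animal_id!r} of {rec.animal_id!r} is female")
            dam = recs.get(rec.dam_id) if rec.dam_id else None
            if dam is not None and dam.sex == "male":
                raise PedigreeError(f"dam {dam.animal_id!r} of {rec.animal_id!r} is male")
        self._records = recs
        self._index_cache: _Index | None = None
        self._kin_memo: dict[tuple[int, int], float] = {}
        self._f_cache: dict[str, float] | None = None
        self._index  # validate acyclicity eagerly

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        try:
            return self._records[animal_id]
        except KeyError:
            raise UnknownAnimalError(f"unknown animal id {animal_id!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def _index(self) -> _Index:
        if self._index_cache is None:
            self._index_cache = _Index(self._records)
        return self._index_cache

    # -- kinship / inbreeding ---------------------------------------------
    def _kinship_idx(self, i: int, j: int) -> float:
        """Kinship between dense positions; -1 denotes an unknown parent.

        Memoized, stack-based evaluation of the classical recursion
        phi(a,a) = (1 + F_a)/2, phi(a,b) = [phi(a, sire_b) + phi(a, dam_b)]/2
        recursing on the topologically later individual.
        """
        memo = self._kin_memo
        sire, dam = self._index.sire, self._index.dam

        def norm(a: int, b: int) -> tuple[int, int]:
            return (a, b) if a <= b else (b, a)

        root = norm(i, j)
        stack = [root]
        while stack:
            key = stack[-1]
            if key in memo:
                stack.pop()
                continue
            a, b = key
            if a < 0 or b < 0:
                memo[key] = 0.0
                stack.pop()
                continue
            if a == b:
                sub = norm(int(sire[a]), int(dam[a]))
                if sub in memo:
                    memo[key] = 0.5 * (1.0 + memo[sub])
                    stack.pop()
                else:
                    stack.append(sub)
                continue
            # larger index b is never an ancestor of a
            k1 = norm(a, int(sire[b]))
            k2 = norm(a, int(dam[b]))
            m1, m2 = memo.get(k1), memo.get(k2)
            if m1 is not None and m2 is not None:
                memo[key] = 0.5 * (m1 + m2)
                stack.pop()
            else:
                if m1 is None:
                    stack.append(k1)
                if m2 is None:
                    stack.append(k2)
        return memo[root]

    def kinship(self, a: str, b: str) -> float:
        """Coefficient of kinship (coancestry) between two animals."""
        idx = self._index
        self[a], self[b]  # raise UnknownAnimalError early
        return self._kinship_idx(idx.pos[a], idx.pos[b])

    def inbreeding_of(self, animal: str) -> float:
        rec = self[animal]
        if rec.sire_id is None or rec.dam_id is None:
            return 0.0
        return self.kinship(rec.sire_id, rec.dam_id)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class InbreedingResult:
    """Per-animal inbreeding coefficients with group summary helpers."""

    values: Mapping[str, float]

    def subset(self, members: Iterable[str]) -> "InbreedingResult":
        return InbreedingResult({a: self.values[a] for a in members})

    @property
    def average(self) -> float:
        return float(np.mean(list(self.values.values())))

    @property
    def maximum(self) -> float:
        return float(np.max(list(self.values.values())))

    @property
    def minimum(self) -> float:
        return float(np.min(list(self.values.values())))


@dataclass(frozen=True)
class CompletenessResult:
    """Per-animal pedigree completeness index at a fixed depth."""

    depth: int
    values: Mapping[str, float]

    @property
    def average(self) -> float:
        return float(np.mean(list(self.values.values())))


# ---------------------------------------------------------------------------
# operations


def topological_order(ped: Pedigree) -> list[str]:
    """Animal ids ordered so that every parent precedes its offspring."""
    return list(ped._index.ids)


def inbreeding(ped: Pedigree, members: Iterable[str] | None = None) -> InbreedingResult:
    """Wright's F for every animal (or a subset): F(x) = kinship(sire, dam).

    Founders and animals with an unknown parent have F = 0.
    """
    ids = list(members) if members is not None else topological_order(ped)
    return InbreedingResult({a: ped.inbreeding_of(a) for a in ids})


def kinship(ped: Pedigree, a: str, b: str) -> float:
    return ped.kinship(a, b)


def average_relationship(ped: Pedigree, members: Iterable[str]) -> float:
    """Mean additive relationship a_ij = 2*kinship over unordered pairs.

    Self-pairs are excluded: this is the average relatedness *among* the
    group's members, not the average of the full relationship matrix.
    """
    ids = sorted(set(members))
    if len(ids) < 2:
        raise PedigreeError("average_relationship requires at least 2 members")
    total = 0.0
    npairs = 0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            total += 2.0 * ped.kinship(a, b)
            npairs += 1
    return total / npairs


def _known_per_generation(ped: Pedigree, root: str | None, depth: int) -> np.ndarray:
    """Count known ancestors per generation for the line rooted at a parent.

    Generation 1 holds the parent itself (1 slot on that side), generation
    g holds 2^(g-1) slots.
    """
    known = np.zeros(depth, dtype=np.int64)
    stack = [(root, 1)]
    while stack:
        aid, gen = stack.pop()
        if aid is None or gen > depth:
            continue
        known[gen - 1] += 1
        rec = ped[aid]
        stack.append((rec.sire_id, gen + 1))
        stack.append((rec.dam_id, gen + 1))
    return known


def pci(ped: Pedigree, animal: str, depth: int = 5) -> float:
    """Pedigree completeness index: harmonic mean of per-line completeness.

    Each parental line's completeness is the mean over generations
    1..depth of the proportion of known ancestors in that generation on
    that side; the index is 2*Cp*Cm/(Cp+Cm), zero when either line is
    entirely unknown.  Complete pedigrees score 1; a missing parent
    scores 0.
    """
    if depth < 1:
        raise PedigreeError("depth must be >= 1")
    rec = ped[animal]
    slots = 2 ** np.arange(depth)  # per-side slots in generations 1..depth
    c_lines = []
    for parent in (rec.sire_id, rec.dam_id):
        known = _known_per_generation(ped, parent, depth)
        c_lines.append(float(np.mean(known / slots)))
    c_pat, c_mat = c_lines
    if c_pat == 0.0 or c_mat == 0.0:
        return 0.0
    return 2.0 * c_pat * c_mat / (c_pat + c_mat)


def completeness(ped: Pedigree, members: Iterable[str], depth: int = 5) -> CompletenessResult:
    return CompletenessResult(depth, {a: pci(ped, a, depth) for a in members})


def make_pseudo_founder(ped: Pedigree, animal: str) -> Pedigree:
    """Return a new pedigree with the animal's parent links removed.

    The former parents keep their records; the input pedigree is not
    modified.  Applying this to a founder returns an equivalent pedigree.
    """
    rec = ped[animal]
    records = dict(ped._records)
    records[animal] = dataclasses.replace(rec, sire_id=None, dam_id=None)
    return Pedigree(records.values())


def ancestors_of(ped: Pedigree, members: Iterable[str]) -> set[str]:
    """All animals reachable upward from the given ids (excluding them)."""
    seen: set[str] = set()
    stack = []
    for m in members:
        rec = ped[m]
        stack.extend(p for p in (rec.sire_id, rec.dam_id) if p is not None)
    while stack:
        aid = stack.pop()
        if aid in seen:
            continue
        seen.add(aid)
        rec = ped[aid]
        stack.extend(p for p in (rec.sire_id, rec.dam_id) if p is not None)
    return seen


def descendants_of(ped: Pedigree, animal: str) -> set[str]:
    """All animals reachable downward from the given id (excluding it)."""
    children: dict[str, list[str]] = {}
    for rec in ped._records.values():
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None:
                children.setdefault(parent, []).append(rec.animal_id)
    seen: set[str] = set()
    stack = list(children.get(animal, []))
    while stack:
        aid = stack.pop()
        if aid in seen:
            continue
        seen.add(aid)
        stack.extend(children.get(aid, []))
    return seen


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["animal", "sire", "dam", "birth_year", "sex", "gait", "role"]


def _clean_id(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in UNKNOWN_TOKENS else s


def read_pedigree(path, sep: str | None = None, permissive_parents: bool = False) -> Pedigree:
    """Read a delimited pedigree file (comma or tab, auto-detected).

    Requires columns ``animal``, ``sire``, ``dam``; accepts ``birth_year``,
    ``sex``, ``gait`` and ``role``.  Unknown parents may be encoded as an
    empty field, "0" or "NA".  Row order is irrelevant.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file {path} lacks columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        aid = _clean_id(row.animal)
        if aid is None:
            raise PedigreeError("row with empty animal id")
        year = _clean_id(getattr(row, "birth_year", None))
        sex = (_clean_id(getattr(row, "sex", None)) or "unknown").lower()
        gait = (_clean_id(getattr(row, "gait", None)) or "unknown").lower()
        role = (_clean_id(getattr(row, "role", None)) or "ancestor_only").lower()
        records.append(
            PedigreeRecord(
                animal_id=aid,
                sire_id=_clean_id(row.sire),
                dam_id=_clean_id(row.dam),
                birth_year=int(year) if year is not None else None,
                sex=_SEX_ALIASES.get(sex, "unknown"),
                gait=gait if gait in _GAITS else "unknown",
                role=role if role in _ROLES else "ancestor_only",
            )
        )
    return Pedigree(records, permissive_parents=permissive_parents)


def write_pedigree(ped: Pedigree, path, sep: str = "\t") -> None:
    """Write the standard dialect deterministically (topological order)."""
    rows = []
    for aid in topological_order(ped):
        rec = ped[aid]
        rows.append(
            {
                "animal": rec.animal_id,
                "sire": rec.sire_id or "",
                "dam": rec.dam_id or "",
                "birth_year": "" if rec.birth_year is None else rec.birth_year,
                "sex": rec.sex,
                "gait": rec.gait,
                "role": rec.role,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(Path(path), sep=sep, index=False)
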