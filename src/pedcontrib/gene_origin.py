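"""Probabilities of gene origin: raw and marginal ancestral contributions.

The raw contribution q_k of an individual k to a reference cohort is the
expected fraction of the cohort's gene pool descending from k, obtained by
halving along every parent link (nothing flows through an unknown parent).

Marginal contributions follow the iterative greedy decomposition of
Boichard and colleagues: at each round the candidate with the largest
contribution *not yet explained* by previously selected ancestors is
selected, p_k = q_k * (1 - sum a_i), where the a_i are the raw
contributions of the already-selected ancestors to candidate k in the
current pedigree; the selected ancestor is then made a pseudo-founder
(parent links cut) so its own ancestry cannot be double counted.  The
resulting marginals are orthogonal and sum to at most 1, with equality
when every founder of the cohort's pedigree is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PedigreeError
from .pedigree import Pedigree

__all__ = [
    "StopRule",
    "MarginalDecomposition",
    "PoolCoverage",
    "ContributionMatrix",
    "raw_contribution",
    "cohort_contributions",
    "marginal_decomposition",
    "pool_coverage",
    "contribution_matrix",
]


# ---------------------------------------------------------------------------
# level-wise graph passes (vectorized over one topological level at a time)


def _forward_pass(sire, dam, level_groups, sources: np.ndarray) -> np.ndarray:
    """Genetic contribution of a *set* of individuals to every animal.

    ``sources`` is a boolean mask; source nodes are clamped to 1.  Because
    selected ancestors are pseudo-founders in the pruned pedigree, the
    clamped combined pass equals the sum of the individual contributions
    of each source (their downward path sets are disjoint at the sources).
    """
    v = np.zeros(len(sire))
    v[sources] = 1.0
    for idx in level_groups[1:]:
        idx = idx[~sources[idx]]
        if idx.size == 0:
            continue
        s, d = sire[idx], dam[idx]
        vs = np.where(s >= 0, v[np.maximum(s, 0)], 0.0)
        vd = np.where(d >= 0, v[np.maximum(d, 0)], 0.0)
        v[idx] = 0.5 * (vs + vd)
    return v


def _backward_pass(sire, dam, level_groups, cohort_idx: np.ndarray) -> np.ndarray:
    """Average contribution of every animal to the cohort, in one sweep.

    Pushes 1/|cohort| of weight from each member up the parent links;
    the result at k equals mean_j c(k -> j) over cohort members j.
    """
    n = len(sire)
    w = np.zeros(n)
    np.add.at(w, cohort_idx, 1.0 / len(cohort_idx))
    for idx in reversed(level_groups):
        half = 0.5 * w[idx]
        for parents in (sire[idx], dam[idx]):
            ok = parents >= 0
            if ok.any():
                np.add.at(w, parents[ok], half[ok])
    return w


# ---------------------------------------------------------------------------
# public types


@dataclass(frozen=True)
class StopRule:
    """Stopping criterion for the iterative decomposition.

    Selection stops when the cumulative explained fraction reaches
    ``cumulative``, when ``max_ancestors`` have been selected, or when the
    candidate pool is exhausted, whichever comes first.
    """

    cumulative: float | None = 0.99
    max_ancestors: int | None = None

    def __post_init__(self):
        if self.cumulative is not None and not (0.0 < self.cumulative <= 1.0):
            raise ValueError(f"cumulative threshold must be in (0, 1], got {self.cumulative}")
        if self.max_ancestors is not None and self.max_ancestors < 1:
            raise ValueError("max_ancestors must be >= 1")


@dataclass(frozen=True)
class DecompositionEntry:
    ancestor_id: str
    raw_contribution: float
    marginal_contribution: float


@dataclass(frozen=True)
class MarginalDecomposition:
    """Ordered marginal contributions of selected ancestors to one cohort."""

    cohort: str
    entries: tuple[DecompositionEntry, ...]

    @property
    def ancestors(self) -> list[str]:
        return [e.ancestor_id for e in self.entries]

    @property
    def marginals(self) -> np.ndarray:
        return np.array([e.marginal_contribution for e in self.entries])

    @property
    def cumulative_explained(self) -> float:
        return float(self.marginals.sum()) if self.entries else 0.0


@dataclass(frozen=True)
class PoolCoverage:
    """Minimal ancestor counts explaining given fractions of the gene pool."""

    counts: dict[float, int | None]  # None: threshold unreachable
    largest_marginal: float

    def __getitem__(self, threshold: float) -> int | None:
        return self.counts[threshold]


class ContributionMatrix:
    """Ancestor x cohort matrix of marginal contributions.

    Cells are missing (NaN) for ancestors not selected in a cohort's
    decomposition — distinct from a selected ancestor whose marginal
    rounds to 0.  Row averages are taken over non-missing cells only.
    """

    def __init__(self, frame: pd.DataFrame, windows: dict[str, tuple[int, int]], group: str = ""):
        if list(frame.columns) != list(windows):
            raise ValueError("frame columns and window labels differ")
        self.frame = frame.astype(float)
        self.windows = dict(windows)
        self.group = group

    @property
    def ancestors(self) -> list[str]:
        return list(self.frame.index)

    @property
    def row_averages(self) -> pd.Series:
        return self.frame.mean(axis=1, skipna=True)

    def row(self, ancestor: str) -> pd.Series:
        return self.frame.loc[ancestor]

    def sorted_by_average(self) -> "ContributionMatrix":
        order = self.row_averages.sort_values(ascending=False, kind="stable").index
        return ContributionMatrix(self.frame.loc[order], self.windows, self.group)

    # -- serialization ----------------------------------------------------
    def to_tidy(self) -> pd.DataFrame:
        tidy = self.frame.stack().rename("marginal").reset_index()
        tidy.columns = ["ancestor", "cohort", "marginal"]
        return tidy

    def to_wide(self, path=None, decimals: int = 3):
        """Wide table with '-' for missing, formatted like the study tables."""
        out = self.frame.round(decimals).map(
            lambda v: "-" if pd.isna(v) else f"{v:.{decimals}f}"
        )
        out["ave"] = self.row_averages.map(lambda v: "-" if pd.isna(v) else f"{v:.{decimals}f}")
        out.index.name = "ancestor"
        if path is not None:
            out.to_csv(path, sep="\t")
        return out

    @classmethod
    def from_wide(cls, source, group: str = "", century_pivot: int = 50) -> "ContributionMatrix":
        """Parse a wide table ('-' = missing); drops any 'ave' column.

        Window labels look like ``93/95``; two-digit years at or above
        ``century_pivot`` are read as 19xx, below as 20xx.
        """
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
            source, sep="\t", index_col=0, na_values=["-"], dtype=str
        )
        df = df.drop(columns=[c for c in df.columns if c.lower() in ("ave", "ave.")])
        df = df.astype(float)

        def year(two_digit: str) -> int:
            y = int(two_digit)
            return 1900 + y if y >= century_pivot else 2000 + y

        windows = {}
        for label in df.columns:
            a, b = str(label).split("/")
            windows[label] = (year(a), year(b))
        return cls(df, windows, group)


# ---------------------------------------------------------------------------
# operations


def cohort_contributions(ped: Pedigree, cohort: Iterable[str]) -> pd.Series:
    """Raw contribution of every animal to the cohort (one backward sweep)."""
    idx = ped._index
    members = sorted(set(cohort))
    if not members:
        raise PedigreeError("empty cohort")
    cohort_idx = np.array([idx.pos[m] for m in members])
    q = _backward_pass(idx.sire, idx.dam, idx.level_groups, cohort_idx)
    return pd.Series(q, index=idx.ids)


def raw_contribution(ped: Pedigree, ancestor: str, cohort: Iterable[str]) -> float:
    """Expected share of the cohort's gene pool descending from one animal."""
    idx = ped._index
    members = sorted(set(cohort))
    if not members:
        raise PedigreeError("empty cohort")
    ped[ancestor]
    sources = np.zeros(len(idx.ids), dtype=bool)
    sources[idx.pos[ancestor]] = True
    v = _forward_pass(idx.sire, idx.dam, idx.level_groups, sources)
    return float(np.mean([v[idx.pos[m]] for m in members]))


def marginal_decomposition(
    ped: Pedigree,
    cohort: Iterable[str],
    stop: StopRule | None = None,
    label: str = "",
) -> MarginalDecomposition:
    """Greedy orthogonal decomposition of a cohort's gene pool by ancestor.

    Candidates are the animals that are ancestors of at least one cohort
    member in the current (pruned) pedigree, excluding cohort members and
    already-selected ancestors.  Ties on the marginal are broken by
    earlier birth year, then lexicographic id, making runs reproducible
    and independent of input record order.
    """
    stop = stop or StopRule()
    idx = ped._index
    members = sorted(set(cohort))
    if not members:
        raise PedigreeError("empty cohort")
    n = len(idx.ids)
    cohort_idx = np.array([idx.pos[m] for m in members])
    in_cohort = np.zeros(n, dtype=bool)
    in_cohort[cohort_idx] = True

    # local, prunable copies; levels from the full pedigree stay valid
    # because pruning only removes edges
    sire = idx.sire.copy()
    dam = idx.dam.copy()
    selected_mask = np.zeros(n, dtype=bool)
    birth = np.where(np.isnan(idx.birth_year), np.inf, idx.birth_year)

    entries: list[DecompositionEntry] = []
    cumulative = 0.0
    tol = 1e-12
    while True:
        if stop.max_ancestors is not None and len(entries) >= stop.max_ancestors:
            break
        if stop.cumulative is not None and cumulative >= stop.cumulative - tol:
            break
        q = _backward_pass(sire, dam, idx.level_groups, cohort_idx)
        candidates = np.flatnonzero((q > tol) & ~in_cohort & ~selected_mask)
        if candidates.size == 0:
            break
        explained = _forward_pass(sire, dam, idx.level_groups, selected_mask)
        p = q[candidates] * np.maximum(1.0 - explained[candidates], 0.0)
        pmax = p.max()
        if pmax <= tol:
            break
        tied = candidates[p >= pmax - tol]
        k = min(tied, key=lambda c: (birth[c], idx.ids[c]))
        p_k = float(q[k] * max(1.0 - explained[k], 0.0))
        entries.append(DecompositionEntry(idx.ids[k], float(q[k]), p_k))
        cumulative += p_k
        selected_mask[k] = True
        sire[k] = -1
        dam[k] = -1
    return MarginalDecomposition(label, tuple(entries))


def pool_coverage(
    dec: MarginalDecomposition, thresholds: Sequence[float] = (0.50, 0.75, 0.99)
) -> PoolCoverage:
    """Smallest n with cumulative marginals >= each threshold (None if unreached)."""
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0, 1]")
    cum = np.cumsum(dec.marginals) if dec.entries else np.array([])
    counts: dict[float, int | None] = {}
    for t in thresholds:
        hit = np.flatnonzero(cum >= t - 1e-12)
        counts[t] = int(hit[0]) + 1 if hit.size else None
    largest = float(dec.marginals.max()) if dec.entries else 0.0
    return PoolCoverage(counts, largest)


def contribution_matrix(ped: Pedigree, cohorts, stop: StopRule | None = None) -> ContributionMatrix:
    """Run the decomposition per cohort and assemble the ancestor x cohort matrix.

    ``cohorts`` is a sequence of :class:`pedcontrib.cohorts.Cohort`.
    Non-selected cells are missing (NaN); row averages skip them.
    """
    columns: dict[str, pd.Series] = {}
    windows: dict[str, tuple[int, int]] = {}
    groups = {c.group for c in cohorts}
    for c in cohorts:
        dec = marginal_decomposition(ped, c.members, stop=stop, label=c.label)
        columns[c.window_label] = pd.Series(
            {e.ancestor_id: e.marginal_contribution for e in dec.entries}
        )
        windows[c.window_label] = (c.year_start, c.year_end)
    frame = pd.DataFrame(columns)
    frame = frame.loc[frame.mean(axis=1, skipna=True).sort_values(ascending=False, kind="stable").index]
    group = groups.pop() if len(groups) == 1 else "mixed"
    return ContributionMatrix(frame, windows, group)
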