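"""Case-control comparison of ancestral contributions.

High-contributing ancestors (average non-missing contribution >= 0.5% in
either group, present in at least two non-overlapping cohort windows) are
tested with a paired two-tailed t-test of their per-window contributions
to affected versus control cohorts.  A window enters the pairing when
either side has a value; the missing side counts as zero contribution
(an ancestor not selected for a cohort contributed nothing marginal to
it).  Benjamini-Hochberg flags are attached at 5% and 10% FDR.

The stage is exposed both as plain functions and as a small model /
results pair: ``ContributionComparison(affected, control).fit()`` returns
a :class:`ContributionComparisonResults` whose ``summary()`` is the
familiar DF / t / P / FDR / group table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError
from .gene_origin import ContributionMatrix

__all__ = [
    "SelectionRule",
    "AncestorTestResult",
    "select_candidate_ancestors",
    "paired_t",
    "bh_fdr",
    "run_comparison",
    "ContributionComparison",
    "ContributionComparisonResults",
]


@dataclass(frozen=True)
class SelectionRule:
    """Eligibility rule for ancestors entering the paired comparison."""

    min_avg_contribution: float = 0.005
    min_nonoverlapping_cohorts: int = 2

    def __post_init__(self):
        if not (0.0 < self.min_avg_contribution < 1.0):
            raise ValueError("min_avg_contribution must be in (0, 1)")
        if self.min_nonoverlapping_cohorts < 1:
            raise ValueError("min_nonoverlapping_cohorts must be >= 1")


@dataclass(frozen=True)
class AncestorTestResult:
    """Paired t-test outcome for one ancestor (affected minus control)."""

    ancestor_id: str
    n_pairs: int
    t: float
    p: float
    significant_p05: bool
    fdr05: bool
    fdr10: bool
    direction: str  # "affected" | "control" | "ns"
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n_pairs - 1


def _max_disjoint_windows(windows: Sequence[tuple[int, int]]) -> int:
    """Size of the largest pairwise-disjoint subset of year intervals.

    Classic greedy interval scheduling: sort by end year, keep every
    interval starting after the last kept end.
    """
    count, last_end = 0, None
    for start, end in sorted(windows, key=lambda w: w[1]):
        if last_end is None or start > last_end:
            count += 1
            last_end = end
    return count


def select_candidate_ancestors(
    affected: ContributionMatrix,
    control: ContributionMatrix,
    rule: SelectionRule | None = None,
) -> list[str]:
    """Ancestors meeting the average-contribution and disjoint-window rule.

    An ancestor qualifies if, in either matrix, its average over
    non-missing cells reaches the threshold AND it was selected in at
    least ``min_nonoverlapping_cohorts`` cohorts whose birth-year windows
    are pairwise disjoint (93/95 and 96/98 are disjoint; 93/95 and 94/96
    are not).
    """
    rule = rule or SelectionRule()
    if list(affected.windows.items()) != list(control.windows.items()):
        raise ValueError("affected and control matrices have different cohort axes")
    chosen = []
    for anc in sorted(set(affected.ancestors) | set(control.ancestors)):
        for m in (affected, control):
            if anc not in m.frame.index:
                continue
            row = m.row(anc)
            present = row.notna()
            if not present.any() or row[present].mean() < rule.min_avg_contribution:
                continue
            windows = [m.windows[c] for c in row.index[present]]
            if _max_disjoint_windows(windows) >= rule.min_nonoverlapping_cohorts:
                chosen.append(anc)
                break
    return chosen


def paired_t(row_affected: pd.Series, row_control: pd.Series) -> tuple[float, float, int]:
    """Paired two-tailed t-test under the zero-fill union pairing.

    Returns (t, p, n_pairs).  A window contributes a pair when either
    row is non-missing there; the missing side is zero.  Raises
    :class:`DegenerateTestError` when all differences are equal (zero
    variance) and ``ValueError`` with fewer than two usable pairs.
    """
    a, c = row_affected, row_control
    if not a.index.equals(c.index):
        raise ValueError("rows are on different window axes")
    use = a.notna() | c.notna()
    d = (a[use].fillna(0.0) - c[use].fillna(0.0)).to_numpy()
    n = len(d)
    if n < 2:
        raise ValueError(f"fewer than 2 usable pairs (got {n})")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTestError("all paired differences identical; zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), n


def bh_fdr(p_values: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def run_comparison(
    affected: ContributionMatrix,
    control: ContributionMatrix,
    rule: SelectionRule | None = None,
    alpha: float = 0.05,
) -> list[AncestorTestResult]:
    """Select ancestors, test each, classify, and attach FDR flags.

    Output is sorted affected-significant first, then control-significant,
    then non-significant, by |t| descending within each block.  Degenerate
    tests (zero-variance differences) are reported but unclassified.
    """
    ancestors = select_candidate_ancestors(affected, control, rule)
    raw: list[dict] = []
    for anc in ancestors:
        row_a = affected.row(anc) if anc in affected.frame.index else pd.Series(
            np.nan, index=affected.frame.columns
        )
        row_c = control.row(anc) if anc in control.frame.index else pd.Series(
            np.nan, index=control.frame.columns
        )
        try:
            t, p, n = paired_t(row_a, row_c)
            raw.append(dict(ancestor_id=anc, n_pairs=n, t=t, p=p, degenerate=False))
        except DegenerateTestError:
            n = int((row_a.notna() | row_c.notna()).sum())
            raw.append(dict(ancestor_id=anc, n_pairs=n, t=np.nan, p=np.nan, degenerate=True))
    testable = [r for r in raw if not r["degenerate"]]
    pvals = [r["p"] for r in testable]
    flags05 = bh_fdr(pvals, 0.05) if pvals else np.zeros(0, dtype=bool)
    flags10 = bh_fdr(pvals, 0.10) if pvals else np.zeros(0, dtype=bool)
    fdr = {r["ancestor_id"]: (bool(f5), bool(f10)) for r, f5, f10 in zip(testable, flags05, flags10)}
    results = []
    for r in raw:
        if r["degenerate"]:
            sig, direction, f5, f10 = False, "ns", False, False
        else:
            sig = r["p"] <= alpha
            direction = "affected" if sig and r["t"] > 0 else ("control" if sig and r["t"] < 0 else "ns")
            f5, f10 = fdr[r["ancestor_id"]]
        results.append(
            AncestorTestResult(
                ancestor_id=r["ancestor_id"], n_pairs=r["n_pairs"], t=r["t"], p=r["p"],
                significant_p05=sig, fdr05=f5, fdr10=f10, direction=direction,
                degenerate=r["degenerate"],
            )
        )
    order = {"affected": 0, "control": 1, "ns": 2}
    results.sort(key=lambda r: (order[r.direction], -abs(r.t) if np.isfinite(r.t) else 0.0))
    return results


# ---------------------------------------------------------------------------
# model / results surface


class ContributionComparison:
    """Paired comparison of ancestral contributions between two groups.

    Parameters
    ----------
    affected, control
        Contribution matrices sharing the same cohort-window axis.
    rule
        Ancestor eligibility rule (defaults: average >= 0.5%, two
        non-overlapping windows).
    alpha
        Two-sided significance level for classification.
    """

    def __init__(
        self,
        affected: ContributionMatrix,
        control: ContributionMatrix,
        rule: SelectionRule | None = None,
        alpha: float = 0.05,
    ):
        self.affected = affected
        self.control = control
        self.rule = rule or SelectionRule()
        self.alpha = alpha

    def fit(self) -> "ContributionComparisonResults":
        results = run_comparison(self.affected, self.control, self.rule, self.alpha)
        return ContributionComparisonResults(self, results)


class ContributionComparisonResults:
    """Per-ancestor test results with a Table-5-style summary."""

    def __init__(self, model: ContributionComparison, results: list[AncestorTestResult]):
        self.model = model
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def __getitem__(self, ancestor_id: str) -> AncestorTestResult:
        for r in self.results:
            if r.ancestor_id == ancestor_id:
                return r
        raise KeyError(ancestor_id)

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return sum(r.significant_p05 for r in self.results)

    @property
    def n_affected(self) -> int:
        return sum(r.direction == "affected" for r in self.results)

    @property
    def n_control(self) -> int:
        return sum(r.direction == "control" for r in self.results)

    @staticmethod
    def _p_bound(p: float) -> str:
        if not np.isfinite(p):
            return "degenerate"
        for bound in (0.001, 0.002, 0.01, 0.02, 0.05):
            if p < bound:
                return f"< {bound:g}"
        return "N.S."

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "ancestor": r.ancestor_id,
                    "df": r.df,
                    "t": round(r.t, 4) if np.isfinite(r.t) else np.nan,
                    "p": r.p,
                    "p_bound": self._p_bound(r.p),
                    "fdr": "*" if r.fdr05 else ("#" if r.fdr10 else ""),
                    "group": {"affected": "Affected", "control": "Control", "ns": "-"}[r.direction],
                }
            )
        return pd.DataFrame(rows).set_index("ancestor")

    def to_table(self, path) -> None:
        self.summary().to_csv(path, sep="\t")
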