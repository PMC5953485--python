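"""Synthetic pedigrees and liability-threshold disease status.

The generator emulates the structure of a closed racehorse registry:
founders, overlapping generations, heavily skewed stallion usage (a
truncated geometric distribution over seniority-ranked eligible sires)
and one dam per foal per year.  Disease status comes from a
liability-threshold model: breeding values follow the pedigree with
additive variance h2, environmental residuals make the liability
standard normal, and cases are the animals in the case birth window
whose liability exceeds the prevalence-matched threshold.  A "risk sire"
family effect can be planted by shifting the liability of every
descendant of a designated (or automatically chosen, most-used) sire.

Every stochastic operation is reproducible from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import PedigreeError
from .pedigree import Pedigree, PedigreeRecord, descendants_of, topological_order

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "assign_phenotypes",
    "PhenotypeResult",
    "choose_risk_sire",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic pedigree + disease generator.

    Defaults give a registry of roughly 5,000 animals with births from
    1961 to 2007 and a 15-year case window (1993-2007), mirroring the
    scale of the study pedigrees.
    """

    seed: int
    n_founders: int = 100
    years: tuple[int, int] = (1958, 2007)
    matings_per_year: int = 100
    offspring_per_mating: int = 1
    sire_skew: float = 0.2
    h2_liability: float = 0.15
    sire_family_effect: float = 0.0
    risk_sire: str | None = None
    risk_family_share: float | None = 0.10
    prevalence: float = 0.05
    control_ratio: int = 5
    case_years: tuple[int, int] = (1993, 2007)
    sire_age: tuple[int, int] = (3, 24)
    dam_age: tuple[int, int] = (3, 20)

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.years[1] < self.years[0]:
            raise ValueError("years reversed")
        if not (0.0 <= self.sire_skew < 1.0):
            raise ValueError("sire_skew must be in [0, 1)")
        if not (0.0 <= self.h2_liability <= 1.0):
            raise ValueError("h2_liability must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.matings_per_year < 1 or self.offspring_per_mating < 1:
            raise ValueError("matings_per_year and offspring_per_mating must be >= 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Generate a multi-generation pedigree with popular-sire structure.

    Founders (half male, half female) are born in ``years[0]``.  Every
    male receives a persistent popularity score at birth; each later
    year, eligible sires are ranked by score and drawn with probability
    proportional to (1-skew)^rank (so a popular stallion dominates while
    at stud and is succeeded by the next-ranked one when he ages out),
    while dams are drawn uniformly without replacement within the year.
    Years with no eligible parents produce no births.
    """
    rng = np.random.default_rng([int(cfg.seed), 11])
    first, last = cfg.years
    records: list[PedigreeRecord] = []
    males: list[tuple[int, str, float]] = []  # (birth_year, id, popularity)
    females: list[tuple[int, str]] = []
    for i in range(cfg.n_founders):
        sex = "male" if i % 2 == 0 else "female"
        aid = f"F{i + 1:04d}"
        records.append(PedigreeRecord(aid, None, None, first, sex))
        if sex == "male":
            males.append((first, aid, float(rng.random())))
        else:
            females.append((first, aid))

    any_births = False
    for year in range(first + 1, last + 1):
        sires = [(a, pop) for by, a, pop in males if cfg.sire_age[0] <= year - by <= cfg.sire_age[1]]
        dams = [a for by, a in females if cfg.dam_age[0] <= year - by <= cfg.dam_age[1]]
        if not sires or not dams:
            continue
        any_births = True
        sires.sort(key=lambda s: (-s[1], s[0]))
        n_mat = min(cfg.matings_per_year, len(dams))
        ranks = np.arange(len(sires))
        weights = (1.0 - cfg.sire_skew) ** ranks
        weights /= weights.sum()
        sire_draw = rng.choice(len(sires), size=n_mat, replace=True, p=weights)
        dam_draw = rng.choice(len(dams), size=n_mat, replace=False)
        foal = 0
        for s_i, d_i in zip(sire_draw, dam_draw):
            for _ in range(cfg.offspring_per_mating):
                foal += 1
                aid = f"X{year}_{foal:04d}"
                sex = "male" if rng.random() < 0.5 else "female"
                records.append(PedigreeRecord(aid, sires[s_i][0], dams[d_i], year, sex))
                if sex == "male":
                    males.append((year, aid, float(rng.random())))
                else:
                    females.append((year, aid))
    if last > first and not any_births:
        raise PedigreeError(
            "infeasible config: no eligible sires/dams in any year "
            "(check founder count, age windows and year span)"
        )
    return Pedigree(records)


def choose_risk_sire(
    ped: Pedigree,
    case_years: tuple[int, int],
    target_share: float | None = None,
    recent_within: int | None = 15,
) -> str:
    """Pick the sire whose family will carry the planted liability shift.

    With ``target_share`` None, the most-used sire with at least one
    descendant born in the case window is chosen (progeny count
    descending, then id).  Otherwise the sire whose descendants make up
    the fraction of case-window births closest to ``target_share`` is
    chosen — a popular-but-not-dominant family, which keeps the number
    of cases compatible with per-year contemporary control sampling.
    With ``recent_within`` set, only sires born at most that many years
    before the window start are considered (falling back to all sires if
    none qualifies): a stallion at stud near the case window spreads his
    family evenly over the window instead of compounding into its tail.
    """
    counts: dict[str, int] = {}
    for aid in ped:
        sire = ped[aid].sire_id
        if sire is not None:
            counts[sire] = counts.get(sire, 0) + 1
    window = [
        a for a in ped
        if ped[a].birth_year is not None and case_years[0] <= ped[a].birth_year <= case_years[1]
    ]
    if not window:
        raise PedigreeError("no animals born in the case window")
    candidates = sorted(counts, key=lambda s: (-counts[s], s))
    if target_share is not None and recent_within is not None:
        recent = [
            s for s in candidates
            if ped[s].birth_year is not None
            and ped[s].birth_year >= case_years[0] - recent_within
        ]
        if recent:
            candidates = recent
    best: tuple[float, str] | None = None
    for sire in candidates:
        in_window = sum(
            1 for d in descendants_of(ped, sire)
            if ped[d].birth_year is not None
            and case_years[0] <= ped[d].birth_year <= case_years[1]
        )
        if in_window == 0:
            continue
        if target_share is None:
            return sire
        gap = abs(in_window / len(window) - target_share)
        if best is None or gap < best[0]:
            best = (gap, sire)
    if best is None:
        raise PedigreeError("no sire has descendants in the case window")
    return best[1]


@dataclass(frozen=True)
class PhenotypeResult:
    """Liability-threshold disease outcome for a simulated pedigree."""

    cases: frozenset[str]
    liability: Mapping[str, float]
    threshold: float
    risk_sire: str | None


def assign_phenotypes(ped: Pedigree, cfg: SimulationConfig) -> PhenotypeResult:
    """Draw liabilities down the pedigree and call cases above the threshold.

    Breeding values: founders ~ N(0, h2); offspring get the parent
    average plus a Mendelian-sampling term with variance h2 * (1 - k/4)
    where k is the number of known parents (an unknown parent contributes
    like an unrelated founder).  Residuals are N(0, 1-h2), so liability
    is standard normal in the base population and the case threshold is
    the (1 - prevalence) normal quantile.  The planted sire-family effect
    shifts the liability of every descendant of the risk sire.
    """
    rng = np.random.default_rng([int(cfg.seed), 23])
    h2 = cfg.h2_liability
    order = topological_order(ped)
    u: dict[str, float] = {}
    for aid in order:
        rec = ped[aid]
        mean = 0.0
        known = 0
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None:
                mean += 0.5 * u[parent]
                known += 1
        var = h2 * (1.0 - known / 4.0)
        u[aid] = mean + rng.normal(0.0, np.sqrt(var)) if var > 0 else mean

    shift: set[str] = set()
    risk_sire = cfg.risk_sire
    if cfg.sire_family_effect != 0.0:
        if risk_sire is None:
            risk_sire = choose_risk_sire(ped, cfg.case_years, cfg.risk_family_share)
        shift = descendants_of(ped, risk_sire)

    e_sd = np.sqrt(1.0 - h2)
    threshold = float(stats.norm.ppf(1.0 - cfg.prevalence))
    liability = {}
    cases = set()
    for aid in order:
        li = u[aid] + rng.normal(0.0, e_sd)
        if aid in shift:
            li += cfg.sire_family_effect
        liability[aid] = li
        by = ped[aid].birth_year
        if by is not None and cfg.case_years[0] <= by <= cfg.case_years[1] and li > threshold:
            cases.add(aid)
    return PhenotypeResult(frozenset(cases), liability, threshold, risk_sire)


def simulate_case_control(cfg: SimulationConfig):
    """Pedigree, cases and sampled contemporary controls in one call.

    Returns (ped, cases, controls, phenotype_result).  Controls are
    ``control_ratio`` birth-year-matched non-cases per case.
    """
    from .cohorts import sample_controls

    ped = simulate_pedigree(cfg)
    pheno = assign_phenotypes(ped, cfg)
    first, last = cfg.case_years
    pool = [
        a for a in ped
        if a not in pheno.cases
        and ped[a].birth_year is not None
        and first <= ped[a].birth_year <= last
    ]
    cases = sorted(pheno.cases)
    controls = sample_controls(cases, pool, ped, ratio=cfg.control_ratio,
                               seed=int(np.random.default_rng([int(cfg.seed), 37]).integers(2**31)))
    return ped, cases, controls, pheno


def tag_roles(ped: Pedigree, cases, controls) -> Pedigree:
    """Return a pedigree with case/control roles stamped on the records."""
    cases, controls = set(cases), set(controls)
    recs = []
    for aid in ped:
        rec = ped[aid]
        role = "case" if aid in cases else ("control" if aid in controls else "ancestor_only")
        recs.append(replace(rec, role=role))
    return Pedigree(recs)
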