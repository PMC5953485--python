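"""End-to-end orchestration: cohorts -> descriptives -> contributions ->
comparison -> appearance profiles, with table-shaped outputs and a run log."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .appearance import profiles_table
from .cohorts import build_cohorts, cohort_descriptives
from .compare import ContributionComparison, SelectionRule
from .errors import PedigreeError
from .gene_origin import StopRule, contribution_matrix, marginal_decomposition, pool_coverage
from .pedigree import read_pedigree

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    pedigree: str
    cases: str
    controls: str
    out_dir: str
    first_year: int = 1993
    last_year: int = 2007
    window: int = 3
    stop_cumulative: float | None = 0.99
    stop_max_ancestors: int | None = None
    min_avg_contribution: float = 0.005
    min_nonoverlapping_cohorts: int = 2
    alpha: float = 0.05
    coverage_thresholds: tuple[float, ...] = (0.50, 0.75, 0.99)
    appearance_depth: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _read_ids(path) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines()]
    return [i for i in ids if i and not i.startswith("#")]


def run_full_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline and write table-shaped outputs.

    Returns a name -> path map of everything written.  Any stage failure
    aborts with the stage name attached to the error message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "load inputs"
    try:
        ped = read_pedigree(cfg.pedigree)
        cases = _read_ids(cfg.cases)
        controls = _read_ids(cfg.controls)
        if not cases:
            raise PedigreeError("empty case list")
        if not controls:
            raise PedigreeError("empty control list")

        stage = "cohorts"
        cohorts = build_cohorts(cases, controls, ped, cfg.first_year, cfg.last_year, cfg.window)
        membership = pd.DataFrame(
            [(c.label, c.group, m) for c in cohorts for m in c.members],
            columns=["cohort_label", "group", "animal_id"],
        )
        written["cohorts"] = out / "cohort_membership.tsv"
        membership.to_csv(written["cohorts"], sep="\t", index=False)
        sizes = pd.DataFrame(
            [(c.label, len(c)) for c in cohorts], columns=["cohort", "size_of_cohort"]
        ).set_index("cohort")

        stage = "descriptives"
        desc_rows = []
        for c in cohorts:
            if len(c) == 0:
                continue
            d = cohort_descriptives(c, ped)
            desc_rows.append(asdict(d))
        desc = pd.DataFrame(desc_rows).set_index("label")
        for col in ("avg_inbreeding", "max_inbreeding", "min_inbreeding",
                    "avg_relationship", "avg_pci"):
            desc[col] = desc[col].round(4)
        written["descriptives"] = out / "cohort_descriptives.tsv"
        desc.to_csv(written["descriptives"], sep="\t")
        sizes["size_of_pedigree"] = desc["pedigree_size"].reindex(sizes.index)
        written["cohort_sizes"] = out / "cohort_sizes.tsv"
        sizes.to_csv(written["cohort_sizes"], sep="\t")

        stage = "contributions"
        stop = StopRule(cumulative=cfg.stop_cumulative, max_ancestors=cfg.stop_max_ancestors)
        affected_cohorts = [c for c in cohorts if c.group == "affected" and len(c)]
        control_cohorts = [c for c in cohorts if c.group == "control" and len(c)]
        m_aff = contribution_matrix(ped, affected_cohorts, stop=stop)
        m_con = contribution_matrix(ped, control_cohorts, stop=stop)
        written["contributions_affected"] = out / "contributions_affected.tsv"
        written["contributions_control"] = out / "contributions_control.tsv"
        m_aff.to_wide(written["contributions_affected"])
        m_con.to_wide(written["contributions_control"])

        stage = "pool coverage"
        cov_rows = []
        for c in affected_cohorts + control_cohorts:
            dec = marginal_decomposition(ped, c.members, stop=stop, label=c.label)
            cov = pool_coverage(dec, cfg.coverage_thresholds)
            row = {"cohort": c.label}
            for t in cfg.coverage_thresholds:
                row[f"n_{int(round(t * 100))}pct"] = cov[t]
            row["largest_marginal"] = round(cov.largest_marginal, 3)
            cov_rows.append(row)
        written["pool_coverage"] = out / "pool_coverage.tsv"
        pd.DataFrame(cov_rows).set_index("cohort").to_csv(written["pool_coverage"], sep="\t")

        stage = "comparison"
        rule = SelectionRule(cfg.min_avg_contribution, cfg.min_nonoverlapping_cohorts)
        results = ContributionComparison(m_aff, m_con, rule, cfg.alpha).fit()
        written["paired_tests"] = out / "paired_tests.tsv"
        results.to_table(written["paired_tests"])

        stage = "appearance"
        affected_sig = [r.ancestor_id for r in results if r.direction == "affected"]
        if affected_sig:
            written["appearance"] = out / "appearance_profiles.tsv"
            profiles_table(ped, cases, affected_sig, cfg.appearance_depth).to_csv(
                written["appearance"], sep="\t"
            )

        stage = "run log"
        log = {
            "pedcontrib_version": __version__,
            "python": sys.version.split()[0],
            "config": asdict(cfg),
            "n_cases": len(cases),
            "n_controls": len(controls),
            "n_tested": results.n_tested,
            "n_significant": results.n_significant,
            "n_affected_direction": results.n_affected,
            "n_control_direction": results.n_control,
        }
        written["run_log"] = out / "run_log.json"
        written["run_log"].write_text(json.dumps(log, indent=1, default=str) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return written
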