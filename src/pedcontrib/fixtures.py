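"""Packaged machine-readable copies of the study's printed tables.

Three read-only TSV files ship with the package: the marginal
contribution tables for the control and affected cohorts (41 ancestors x
13 three-year windows, "-" preserved as missing) and the paired t-test
table (DF, t, printed P bound, FDR mark, group, broodmare flag).  A
checksum manifest guards against accidental edits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FixtureError
from .gene_origin import ContributionMatrix

__all__ = ["FixtureSet", "load_fixtures", "fixture_dir"]

_FILES = {
    "control": "contributions_control.tsv",
    "affected": "contributions_affected.tsv",
    "tests": "paired_tests.tsv",
}
_MANIFEST = "manifest.json"


@dataclass(frozen=True)
class FixtureSet:
    """Parsed printed tables: contribution matrices and the test table."""

    affected: ContributionMatrix
    control: ContributionMatrix
    tests: pd.DataFrame

    @property
    def ancestors(self) -> set[str]:
        return set(self.affected.ancestors) | set(self.control.ancestors)


def fixture_dir() -> Path:
    return Path(resources.files("pedcontrib") / "data")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def verify_checksums(data_dir: Path | None = None) -> None:
    """Raise :class:`FixtureError` if any packaged table was modified."""
    base = Path(data_dir) if data_dir is not None else fixture_dir()
    manifest_path = base / _MANIFEST
    if not manifest_path.exists():
        raise FixtureError(f"missing fixture manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for name in _FILES.values():
        path = base / name
        if not path.exists():
            raise FixtureError(f"missing fixture file {path}")
        digest = _sha256(path)
        if digest != manifest.get(name):
            raise FixtureError(
                f"checksum mismatch for {name}: fixtures are read-only data "
                f"(expected {manifest.get(name)}, found {digest})"
            )


def load_fixtures(data_dir: Path | None = None) -> FixtureSet:
    """Load and checksum-verify the packaged tables.

    Contribution values are as printed (3 decimals); the redundant
    printed average column is dropped from the matrices (row averages
    are recomputed from the cells on demand).
    """
    base = Path(data_dir) if data_dir is not None else fixture_dir()
    verify_checksums(base)
    affected = ContributionMatrix.from_wide(base / _FILES["affected"], group="affected")
    control = ContributionMatrix.from_wide(base / _FILES["control"], group="control")
    tests = pd.read_csv(base / _FILES["tests"], sep="\t", index_col=0, keep_default_na=False)
    fs = FixtureSet(affected=affected, control=control, tests=tests)
    if len(fs.ancestors) != 41 or len(tests) != 41:
        raise FixtureError("fixture tables do not contain the expected 41 ancestors")
    if affected.frame.shape[1] != 13 or control.frame.shape[1] != 13:
        raise FixtureError("fixture matrices do not have 13 window columns")
    return fs
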