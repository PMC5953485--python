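import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedcontrib import (
    Cohort,
    Pedigree,
    PedigreeError,
    PedigreeRecord,
    StopRule,
    contribution_matrix,
    make_pseudo_founder,
    marginal_decomposition,
    pool_coverage,
    raw_contribution,
)
from pedcontrib.gene_origin import MarginalDecomposition, DecompositionEntry
from .conftest import rec
from .helpers import gene_drop_contribution, path_contribution


@pytest.fixture
def double_grandsire_ped():
    """G is both the paternal and the maternal grandsire of X."""
    return Pedigree([
        rec("G", sex="male"), rec("B", sex="female"), rec("C", sex="female"),
        rec("S", "G", "B", sex="male"), rec("D", "G", "C", sex="female"),
        rec("X", "S", "D"),
    ])


class TestRawContribution:
    def test_closed_forms(self, trio_ped):
        assert raw_contribution(trio_ped, "X", ["X"]) == 1.0
        assert raw_contribution(trio_ped, "S", ["X"]) == 0.5

    def test_grandsire_single_path(self, halfsib_mating_ped):
        assert raw_contribution(halfsib_mating_ped, "B", ["X"]) == 0.25

    def test_grandsire_both_sides(self, double_grandsire_ped):
        assert raw_contribution(double_grandsire_ped, "G", ["X"]) == 0.5

    def test_empty_cohort_rejected(self, trio_ped):
        with pytest.raises(PedigreeError):
            raw_contribution(trio_ped, "S", [])

    def test_matches_path_enumeration(self, random_ped):
        ped = random_ped(seed=11, years=(1970, 1985), matings_per_year=12)
        members = sorted(ped)[-10:]
        rng = np.random.default_rng(0)
        ancestors = rng.choice(sorted(ped), size=15, replace=False)
        for anc in ancestors:
            expect = np.mean([path_contribution(ped, anc, m) for m in members])
            assert raw_contribution(ped, anc, members) == pytest.approx(expect, abs=1e-12)

    def test_matches_gene_dropping(self, random_ped):
        """Monte-Carlo allele dropping agrees within 3 standard errors."""
        ped = random_ped(seed=12, years=(1970, 1985), matings_per_year=12)
        members = sorted(ped)[-12:]
        rng = np.random.default_rng(1)
        contributions = {
            a: raw_contribution(ped, a, members) for a in ped
        }
        top = sorted(contributions, key=contributions.get, reverse=True)[:3]
        for anc in top:
            est, se = gene_drop_contribution(ped, anc, members, 20_000, rng)
            assert abs(est - contributions[anc]) <= 3 * se + 1e-12


class TestMarginalDecomposition:
    def test_fullsib_family_decomposes_to_parents(self):
        ped = Pedigree([
            rec("S", sex="male", year=1980), rec("D", sex="female", year=1981),
            rec("X1", "S", "D"), rec("X2", "S", "D"), rec("X3", "S", "D"),
        ])
        dec = marginal_decomposition(ped, ["X1", "X2", "X3"], StopRule(cumulative=1.0))
        assert [(e.ancestor_id, e.marginal_contribution) for e in dec.entries] == [
            ("S", 0.5), ("D", 0.5),
        ]  # tie on p broken by earlier birth year
        assert dec.cumulative_explained == pytest.approx(1.0)

    def test_pruned_ancestor_never_selected_with_zero_marginal(self):
        """After the sire is selected, his own sire has nothing left to give."""
        ped = Pedigree([
            rec("G", sex="male"), rec("GD", sex="female"),
            rec("S", "G", "GD", sex="male", year=1980),
            rec("D", sex="female", year=1980),
            rec("X", "S", "D"),
        ])
        dec = marginal_decomposition(ped, ["X"], StopRule(cumulative=1.0))
        assert "S" in dec.ancestors and "D" in dec.ancestors
        assert "G" not in dec.ancestors
        assert dec.cumulative_explained == pytest.approx(1.0)

    def test_adjustment_for_already_explained_share(self):
        """p_k = q_k (1 - sum a_i), hand-expanded on a three-generation toy.

        Cohort {X1, D} with X1 = (S, D), S = (G, B), D = (G, C).  G is the
        top contributor (q = 0.5) and is selected first.  When S comes up,
        its raw share is q_S = 0.25 but half of S's genome descends from
        the already-selected G (a = 0.5), so its marginal must be
        0.25 * (1 - 0.5) = 0.125 — the share of the pool reaching X1
        through S but not through G.
        """
        ped = Pedigree([
            rec("G", sex="male", year=1970), rec("B", sex="female", year=1985),
            rec("C", sex="female", year=1971),
            rec("S", "G", "B", sex="male", year=1980),
            rec("D", "G", "C", sex="female", year=1981),
            rec("X1", "S", "D"),
        ])
        dec = marginal_decomposition(ped, ["X1", "D"], StopRule(cumulative=1.0))
        by_id = {e.ancestor_id: e for e in dec.entries}
        assert dec.ancestors[0] == "G"
        assert by_id["G"].marginal_contribution == pytest.approx(0.5)
        assert by_id["S"].raw_contribution == pytest.approx(0.25)
        assert by_id["S"].marginal_contribution == pytest.approx(0.125)
        assert by_id["C"].marginal_contribution == pytest.approx(0.375)
        assert dec.cumulative_explained == pytest.approx(1.0)

    def test_pseudo_founder_reroutes_contribution(self, double_grandsire_ped):
        """Spec'd primitive: pruning an ancestor removes the paths through it."""
        ped = double_grandsire_ped
        before = raw_contribution(ped, "G", ["X"])
        pruned = make_pseudo_founder(ped, "S")
        after = raw_contribution(pruned, "G", ["X"])
        assert before == pytest.approx(0.5)
        assert after == pytest.approx(0.25)  # only the dam-side path remains

    def test_sum_to_one_on_fully_known_pedigree(self, random_ped):
        ped = random_ped(seed=13)
        members = sorted(a for a in ped if ped[a].birth_year == 1999)[:15]
        dec = marginal_decomposition(ped, members, StopRule(cumulative=1.0))
        assert dec.cumulative_explained == pytest.approx(1.0, abs=1e-9)

    def test_sum_below_one_with_unknown_parents(self, random_ped):
        ped = random_ped(seed=14)
        # sever some dam links: unknown ancestry leaks gene-pool share
        records = []
        for i, aid in enumerate(ped):
            r = ped[aid]
            if i % 7 == 3 and r.dam_id is not None:
                r = PedigreeRecord(r.animal_id, r.sire_id, None, r.birth_year, r.sex)
            records.append(r)
        holey = Pedigree(records, permissive_parents=True)
        members = sorted(a for a in holey if holey[a].birth_year == 1999)[:15]
        dec = marginal_decomposition(holey, members, StopRule(cumulative=1.0))
        assert dec.cumulative_explained <= 1.0 + 1e-9

    def test_marginal_never_exceeds_raw(self, random_ped):
        ped = random_ped(seed=15)
        members = sorted(a for a in ped if ped[a].birth_year == 1998)[:12]
        dec = marginal_decomposition(ped, members, StopRule(max_ancestors=40))
        for e in dec.entries:
            assert e.marginal_contribution <= e.raw_contribution + 1e-12
            assert e.marginal_contribution >= 0.0

    def test_order_invariance(self, random_ped):
        ped = random_ped(seed=16)
        members = sorted(a for a in ped if ped[a].birth_year == 1999)[:10]
        rng = np.random.default_rng(0)
        records = [ped[a] for a in ped]
        rng.shuffle(records)
        shuffled = Pedigree(records)
        d1 = marginal_decomposition(ped, members, StopRule(max_ancestors=25))
        d2 = marginal_decomposition(shuffled, members, StopRule(max_ancestors=25))
        assert d1.ancestors == d2.ancestors
        assert np.allclose(d1.marginals, d2.marginals)

    def test_orthogonality_against_public_pruning(self, random_ped):
        """The fast array path agrees with literal make_pseudo_founder replay.

        Replaying the selection sequence through the public primitive and
        recomputing q_k in the pedigree as pruned at each round must
        reproduce the recorded raw contributions.
        """
        ped = random_ped(seed=17, years=(1970, 1985), matings_per_year=12)
        members = sorted(ped)[-8:]
        dec = marginal_decomposition(ped, members, StopRule(max_ancestors=6))
        current = ped
        for entry in dec.entries:
            q = raw_contribution(current, entry.ancestor_id, members)
            assert q == pytest.approx(entry.raw_contribution, abs=1e-12)
            current = make_pseudo_founder(current, entry.ancestor_id)

    def test_bad_threshold_rejected(self, trio_ped):
        with pytest.raises(ValueError):
            StopRule(cumulative=1.5)
        with pytest.raises(ValueError):
            StopRule(cumulative=0.0)


class TestPoolCoverage:
    def test_cumulative_closed_form(self):
        dec = MarginalDecomposition("c", tuple(
            DecompositionEntry(f"A{i}", m, m) for i, m in enumerate([0.6, 0.3, 0.09, 0.01])
        ))
        cov = pool_coverage(dec, [0.5, 0.75, 0.99])
        assert (cov[0.5], cov[0.75], cov[0.99]) == (1, 2, 3)

    def test_unreachable_threshold_flagged(self):
        dec = MarginalDecomposition("c", tuple(
            DecompositionEntry(f"A{i}", m, m) for i, m in enumerate([0.6, 0.35])
        ))
        assert pool_coverage(dec, [0.99])[0.99] is None

    @given(st.lists(st.floats(0.001, 0.2), min_size=1, max_size=30), st.floats(0.05, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_rescan(self, marginals, tau):
        total = sum(marginals)
        if total > 1.0:
            marginals = [m / (total * 1.01) for m in marginals]
        dec = MarginalDecomposition("c", tuple(
            DecompositionEntry(f"A{i}", m, m) for i, m in enumerate(marginals)
        ))
        cov = pool_coverage(dec, [tau])[tau]
        cum = np.cumsum(marginals)
        brute = next((i + 1 for i, c in enumerate(cum) if c >= tau - 1e-12), None)
        assert cov == brute

    def test_counts_nondecreasing_in_threshold(self, random_ped):
        ped = random_ped(seed=18)
        members = sorted(a for a in ped if ped[a].birth_year == 1999)[:10]
        dec = marginal_decomposition(ped, members, StopRule(cumulative=1.0))
        cov = pool_coverage(dec, [0.5, 0.75, 0.99])
        assert cov[0.5] <= cov[0.75] <= cov[0.99]


class TestContributionMatrix:
    def test_single_cohort_equals_decomposition(self, random_ped):
        ped = random_ped(seed=19)
        members = tuple(sorted(a for a in ped if ped[a].birth_year in (1997, 1998, 1999))[:12])
        cohort = Cohort("affected", 1997, 1999, members)
        dec = marginal_decomposition(ped, members, StopRule(max_ancestors=10))
        matrix = contribution_matrix(ped, [cohort], StopRule(max_ancestors=10))
        col = matrix.frame[cohort.window_label].dropna()
        assert set(col.index) == set(dec.ancestors)
        for e in dec.entries:
            assert col[e.ancestor_id] == pytest.approx(e.marginal_contribution)

    def test_row_average_ignores_missing(self, random_ped):
        import pandas as pd

        frame = pd.DataFrame(
            {"93/95": [0.086, 0.1], "96/98": [np.nan, 0.2]}, index=["ID14", "Z"]
        )
        from pedcontrib import ContributionMatrix

        m = ContributionMatrix(frame, {"93/95": (1993, 1995), "96/98": (1996, 1998)})
        assert m.row_averages["ID14"] == pytest.approx(0.086)
        assert m.row_averages["Z"] == pytest.approx(0.15)

    def test_three_cohort_row_averages(self, random_ped):
        ped = random_ped(seed=20)
        cohorts = []
        for start in (1994, 1996, 1998):
            members = tuple(sorted(
                a for a in ped if ped[a].birth_year in range(start, start + 2)
            )[:10])
            cohorts.append(Cohort("affected", start, start + 1, members))
        matrix = contribution_matrix(ped, cohorts, StopRule(max_ancestors=8))
        means = matrix.frame.mean(axis=1, skipna=True)
        for anc in matrix.ancestors:
            cells = [v for v in matrix.frame.loc[anc] if not np.isnan(v)]
            assert means[anc] == pytest.approx(np.mean(cells))

    def test_wide_roundtrip(self, tmp_path, random_ped):
        from pedcontrib import ContributionMatrix

        ped = random_ped(seed=21)
        members = tuple(sorted(a for a in ped if ped[a].birth_year == 1999)[:10])
        matrix = contribution_matrix(
            ped, [Cohort("control", 1997, 1999, members)], StopRule(max_ancestors=6)
        )
        path = tmp_path / "wide.tsv"
        matrix.to_wide(path)
        back = ContributionMatrix.from_wide(path)
        assert back.windows == matrix.windows
        assert np.allclose(back.frame.values, matrix.frame.round(3).values, equal_nan=True)
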