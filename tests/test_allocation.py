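"""Fuzzy-coded trait allocation: worked examples, conservation, additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitseg.allocation import (
    TraitAbundanceMatrix,
    TraitAffinityTable,
    affinities_to_coefficients,
    allocate_taxon_abundance,
    build_trait_abundance_matrix,
    filter_sparse_traits,
    round_half_away,
)
from traitseg.errors import ValidationError


class TestCoefficients:
    @pytest.mark.parametrize(
        "affinities, coded, expected",
        [
            ([1, 3], True, [0.25, 0.75]),        # graded affinities normalise
            ([1, 1], False, [0.5, 0.5]),         # equal-coding fallback, two traits
            ([5, 0, 0], True, [1.0, 0.0, 0.0]),  # single affinity
            ([0, 0], True, [0.0, 0.0]),          # no affinity -> contributes nothing
            ([1, 1, 1, 0], False, [1 / 3, 1 / 3, 1 / 3, 0.0]),
        ],
    )
    def test_normalisation(self, affinities, coded, expected):
        np.testing.assert_allclose(
            affinities_to_coefficients(affinities, coded), expected, atol=1e-15
        )

    @pytest.mark.parametrize("bad", [[1.5, 2], [-1, 3], [6, 0], [np.nan, 1]])
    def test_invalid_affinities_rejected(self, bad):
        with pytest.raises(ValidationError, match="affinity"):
            affinities_to_coefficients(bad, True, taxon="Baetidae", feature="feeding_style")

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8))
    @settings(deadline=None)
    def test_coded_coefficients_sum_to_one_or_zero(self, affinities):
        c = affinities_to_coefficients(affinities, True)
        total = c.sum()
        assert (sum(affinities) == 0 and total == 0) or abs(total - 1.0) < 1e-12
        assert np.all((c >= 0) & (c <= 1))


class TestAllocation:
    def test_worked_mayfly_example(self):
        """Count 8 with affinities 1 and 3 splits into 2 and 6 individuals."""
        c = affinities_to_coefficients([1, 3], True)
        np.testing.assert_array_equal(allocate_taxon_abundance(8, c), [2, 6])

    def test_rounding_rule_half_away_from_zero(self):
        # 7 * 0.25 = 1.75 -> 2 ; 7 * 0.75 = 5.25 -> 5
        np.testing.assert_array_equal(allocate_taxon_abundance(7, [0.25, 0.75]), [2, 5])
        np.testing.assert_array_equal(round_half_away([0.5, 1.5, 2.5, -0.5]), [1, 2, 3, -1])

    def test_zero_count(self):
        np.testing.assert_array_equal(allocate_taxon_abundance(0, [0.25, 0.75]), [0, 0])

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            allocate_taxon_abundance(-1, [1.0])

    @given(
        count=st.integers(0, 10_000),
        affinities=st.lists(st.integers(0, 5), min_size=1, max_size=8).filter(
            lambda a: sum(a) > 0
        ),
    )
    @settings(deadline=None)
    def test_allocation_conserves_count_within_rounding_slack(self, count, affinities):
        """|sum of shares - count| <= T/2 where T counts nonzero coefficients,
        with exact equality when all shares are integral."""
        c = affinities_to_coefficients(affinities, True)
        shares = allocate_taxon_abundance(count, c)
        T = int((c > 0).sum())
        assert abs(int(shares.sum()) - count) <= T / 2
        if np.allclose(count * c, np.round(count * c)):
            assert int(shares.sum()) == count
        assert np.all(shares >= 0)


class TestMatrixBuild:
    def test_worked_example_site(self, feeding_affinity):
        taxa = pd.DataFrame({"site_id": ["US17"], "taxon": ["Baetidae"], "count": [8]})
        m = build_trait_abundance_matrix(taxa, feeding_affinity)
        assert m.data.loc["US17", ("feeding_style", "deposit_feeder")] == 2
        assert m.data.loc["US17", ("feeding_style", "scraper")] == 6

    def test_uncoded_taxon_split_equally(self, feeding_affinity):
        taxa = pd.DataFrame({"site_id": ["s1"], "taxon": ["Physidae"], "count": [9]})
        m = build_trait_abundance_matrix(taxa, feeding_affinity)
        # equal coding 0.5/0.5 over two possessed traits: 4.5 rounds to 5 each
        assert m.data.loc["s1", ("feeding_style", "deposit_feeder")] == 5
        assert m.data.loc["s1", ("feeding_style", "scraper")] == 5

    def test_zero_record_site_gives_zero_row(self, feeding_affinity):
        taxa = pd.DataFrame({"site_id": ["s1"], "taxon": ["Baetidae"], "count": [0]})
        m = build_trait_abundance_matrix(taxa, feeding_affinity)
        assert (m.data.loc["s1"] == 0).all()

    def test_unknown_taxon_strict_and_lenient(self, feeding_affinity):
        taxa = pd.DataFrame(
            {"site_id": ["s1", "s1"], "taxon": ["Baetidae", "Gammaridae"], "count": [8, 4]}
        )
        with pytest.raises(ValidationError, match="Gammaridae"):
            build_trait_abundance_matrix(taxa, feeding_affinity)
        m = build_trait_abundance_matrix(taxa, feeding_affinity, on_unknown="skip")
        assert m.skipped_taxa == ["Gammaridae"]
        assert m.data.loc["s1", ("feeding_style", "scraper")] == 6

    def test_duplicate_site_taxon_rejected(self, feeding_affinity):
        taxa = pd.DataFrame(
            {"site_id": ["s1", "s1"], "taxon": ["Baetidae", "Baetidae"], "count": [8, 4]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            build_trait_abundance_matrix(taxa, feeding_affinity)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_additivity_over_taxa_tables(self, seed):
        """A matrix built from a concatenated record table equals the entrywise
        sum of the matrices built from its parts."""
        feeding_affinity = _fixture_affinity()
        rng = np.random.default_rng(seed)
        taxa_names = feeding_affinity.taxa
        sites = ["a", "b", "c"]
        rows = [
            {"site_id": s, "taxon": t, "count": int(rng.integers(0, 50))}
            for s in sites
            for t in taxa_names
        ]
        full = pd.DataFrame(rows)
        part1 = full[full["taxon"].isin(taxa_names[:2])]
        part2 = full[~full["taxon"].isin(taxa_names[:2])]
        m_full = build_trait_abundance_matrix(full, feeding_affinity).data
        m1 = build_trait_abundance_matrix(part1, feeding_affinity).data
        m2 = build_trait_abundance_matrix(part2, feeding_affinity).data
        combined = m1.add(m2, fill_value=0).astype(int).loc[m_full.index]
        pd.testing.assert_frame_equal(m_full, combined, check_dtype=False)

    def test_determinism(self, feeding_affinity):
        taxa = pd.DataFrame(
            {"site_id": ["s1", "s2"], "taxon": ["Baetidae", "Elmidae"], "count": [8, 13]}
        )
        a = build_trait_abundance_matrix(taxa, feeding_affinity).data
        b = build_trait_abundance_matrix(taxa, feeding_affinity).data
        pd.testing.assert_frame_equal(a, b)


def _fixture_affinity() -> TraitAffinityTable:
    cols = pd.MultiIndex.from_tuples(
        [("feeding_style", "deposit_feeder"), ("feeding_style", "scraper"),
         ("respiration_mode", "gill"), ("respiration_mode", "tegument")],
        names=["feature", "trait"],
    )
    scores = pd.DataFrame(
        [[1, 3, 5, 0], [5, 0, 0, 5], [2, 2, 2, 3]],
        index=pd.Index(["Baetidae", "Elmidae", "Physidae"], name="taxon"),
        columns=cols,
    )
    return TraitAffinityTable(scores=scores)


class TestSparsityFilter:
    def _matrix(self, zeros_in_col0: int, n_sites: int = 80) -> TraitAbundanceMatrix:
        cols = pd.MultiIndex.from_tuples(
            [("feeding_style", "absorber"), ("feeding_style", "scraper")],
            names=["feature", "trait"],
        )
        data = pd.DataFrame(1, index=range(n_sites), columns=cols)
        data.iloc[:zeros_in_col0, 0] = 0
        return TraitAbundanceMatrix(data=data)

    def test_mostly_zero_trait_excluded(self):
        m = filter_sparse_traits(self._matrix(79), max_zero_fraction=0.9)
        assert m.excluded[("feeding_style", "absorber")]
        assert not m.excluded[("feeding_style", "scraper")]
        assert ("feeding_style", "scraper") in m.retained().columns

    def test_everywhere_nonzero_retained_at_any_threshold(self):
        for thr in (0.01, 0.5, 1.0):
            m = filter_sparse_traits(self._matrix(0), max_zero_fraction=thr)
            assert not m.excluded.any()

    def test_threshold_one_is_vacuous(self):
        m = filter_sparse_traits(self._matrix(80), max_zero_fraction=1.0)
        assert not m.excluded.any()

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError, match="max_zero_fraction"):
            filter_sparse_traits(self._matrix(0), max_zero_fraction=0.0)

    def test_explicit_exclude_list_applied(self):
        m = filter_sparse_traits(
            self._matrix(0), exclude=[("feeding_style", "absorber")]
        )
        assert m.excluded[("feeding_style", "absorber")]
        report = m.exclusion_report()
        assert report.loc[report["trait"] == "absorber", "excluded"].item()

    def test_data_preserved_under_flags(self):
        base = self._matrix(79)
        m = filter_sparse_traits(base, max_zero_fraction=0.5)
        pd.testing.assert_frame_equal(m.data, base.data)


class TestCsvRoundTrip:
    def test_affinity_table(self, feeding_affinity, tmp_path):
        path = tmp_path / "affinity.csv"
        feeding_affinity.to_csv(path)
        back = TraitAffinityTable.from_csv(path)
        pd.testing.assert_frame_equal(back.scores, feeding_affinity.scores)
        assert back.uncoded == feeding_affinity.uncoded

    def test_abundance_matrix(self, feeding_affinity, tmp_path):
        taxa = pd.DataFrame(
            {"site_id": ["s1", "s2"], "taxon": ["Baetidae", "Elmidae"], "count": [8, 13]}
        )
        m = build_trait_abundance_matrix(taxa, feeding_affinity)
        path = tmp_path / "abundance.csv"
        m.to_csv(path)
        back = TraitAbundanceMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.data, m.data)
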