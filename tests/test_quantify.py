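"""Normalization, presence filtering, mass fractions and filter weighting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import protpool as pp
from protpool.quantify import QuantifyError, SampleKey
from conftest import pepmap_from_specs, simple_intensity_table


class TestFilterWeights:
    def test_worked_example_90_10(self):
        weights = pp.filter_weights({3.0: 90, 0.8: 10, 0.1: 0})
        assert weights == {3.0: 0.9, 0.8: 0.1, 0.1: 0.0}

    def test_single_filter(self):
        assert pp.filter_weights({3.0: 42}) == {3.0: 1.0}

    def test_direct_formula(self):
        assert pp.filter_weights({3.0: 50, 0.8: 30, 0.1: 20}) == {
            3.0: 0.5, 0.8: 0.3, 0.1: 0.2}

    def test_all_zero_is_error(self):
        with pytest.raises(QuantifyError):
            pp.filter_weights({3.0: 0, 0.8: 0})

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=5).filter(sum))
    def test_weights_sum_to_one(self, counts):
        weights = pp.filter_weights(dict(enumerate(counts)))
        assert abs(sum(weights.values()) - 1.0) < 1e-9


class TestNormalization:
    def _table(self):
        rows = [("a", 1, 3.0, 1, 10.0), ("b", 1, 3.0, 1, 30.0),
                ("c", 1, 3.0, 1, 60.0)]
        return simple_intensity_table(rows, tic=[(1, 3.0, 1, 250.0)])

    def test_factor_is_identified_sum(self):
        assert pp.normalization_factor(self._table(), SampleKey(1, 3.0, 1)) == 100.0

    def test_normalized_intensities_sum_to_one(self):
        table = self._table()
        norm = table.mean_normalized(1, 3.0)
        assert abs(norm.sum() - 1.0) < 1e-12

    def test_empty_sample_is_error(self):
        with pytest.raises(QuantifyError):
            pp.normalization_factor(self._table(), SampleKey(2, 3.0, 1))

    def test_tic_is_database_independent(self):
        table = self._table()
        assert pp.tic_normalization_factor(table, SampleKey(1, 3.0, 1)) == 250.0
        # dropping identified peptides does not change the TIC
        smaller = pp.IntensityTable(table.data.iloc[:1], tic=table.tic)
        assert pp.tic_normalization_factor(smaller, SampleKey(1, 3.0, 1)) == 250.0

    def test_missing_tic_is_error(self):
        table = simple_intensity_table([("a", 1, 3.0, 1, 1.0)])
        with pytest.raises(QuantifyError):
            pp.tic_normalization_factor(table, SampleKey(1, 3.0, 1))

    def test_identification_sweep_degrades_tic_correlation(self):
        """With complete identification the identified-sum equals the TIC
        (r = 1); discarding identified signal can only weaken the
        correlation between the two normalization factors."""
        rng = np.random.default_rng(0)
        n_inj = 8
        full, half, tics = [], [], []
        for i in range(n_inj):
            vals = rng.lognormal(0, 1.5, 200)
            tics.append(vals.sum())
            full.append(vals.sum())
            half.append(np.sort(vals)[-60:].sum())  # 30% identified
        r_full = np.corrcoef(full, tics)[0, 1]
        r_half = np.corrcoef(half, tics)[0, 1]
        assert r_full == pytest.approx(1.0, abs=1e-12)
        assert r_half <= r_full + 1e-12


class TestNormalizationSensitivity:
    @pytest.mark.parametrize(
        "raw,var,expected",
        [(100, 0.16, (92.0, 108.0)), (7.0, 0.0, (7.0, 7.0)),
         (50, 0.16, (46.0, 54.0))],
    )
    def test_examples(self, raw, var, expected):
        assert pp.normalization_sensitivity(raw, var) == pytest.approx(expected)

    def test_negative_intensity_is_error(self):
        with pytest.raises(QuantifyError):
            pp.normalization_sensitivity(-1.0, 0.1)


class TestPresenceFilter:
    def test_partial_observation_dropped(self):
        rows = [("a", 1, 3.0, 1, 5.0), ("a", 1, 3.0, 2, 6.0),
                ("b", 1, 3.0, 1, 1.0), ("b", 1, 3.0, 2, 2.0),
                ("b", 1, 3.0, 3, 3.0), ("a", 1, 3.0, 3, 0.0)]
        table = simple_intensity_table(rows)
        kept = table.presence_filter().data
        # a was seen in 2/3 injections (zero intensity is not observed)
        assert set(kept["peptide"]) == {"b"}

    def test_complete_observation_kept(self):
        rows = [("a", 1, 3.0, i, float(i)) for i in (1, 2, 3)]
        table = simple_intensity_table(rows)
        assert len(table.presence_filter().data) == 3

    def test_single_injection_identity(self):
        rows = [("a", 1, 0.8, 1, 5.0), ("b", 1, 0.8, 1, 2.0)]
        table = simple_intensity_table(rows)
        assert table.presence_filter().data.equals(table.data)


class TestTaxonNormalize:
    def test_proportions(self):
        pm = pepmap_from_specs({
            "a": (("diatom",), ("ribosomal",)),
            "b": (("diatom",), ("none",)),
            "c": (("diatom",), ("none",)),
            "x": (("diatom", "haptophyte"), ("none",)),
        })
        rows = [("a", 1, 3.0, 1, 2.0), ("b", 1, 3.0, 1, 3.0),
                ("c", 1, 3.0, 1, 5.0), ("x", 1, 3.0, 1, 100.0)]
        table = simple_intensity_table(rows)
        norm = pp.taxon_normalize(table, "diatom", pm, 1, 3.0)
        assert norm.to_dict() == pytest.approx({"a": 0.2, "b": 0.3, "c": 0.5})

    def test_no_unique_peptides_is_error(self):
        pm = pepmap_from_specs({"x": (("t1", "t2"), ("none",))})
        table = simple_intensity_table([("x", 1, 3.0, 1, 1.0)])
        with pytest.raises(QuantifyError):
            pp.taxon_normalize(table, "t1", pm, 1, 3.0)


class TestMassFraction:
    def _fixture(self):
        pm = pepmap_from_specs({
            "a": (("diatom",), ("ribosomal",)),
            "b": (("diatom",), ("ribosomal",)),
            "c": (("diatom",), ("none",)),
            "d": (("diatom",), ("none",)),
        })
        rows = [(p, 1, 3.0, 1, 1.0) for p in "abcd"]
        return pm, simple_intensity_table(rows)

    def test_toy_half(self):
        pm, table = self._fixture()
        est = pp.mass_fraction(table, "diatom", "ribosomal", 1, 3.0, pm)
        assert est.value == pytest.approx(0.5)
        assert est.n_peptides == 2

    def test_all_pool_is_one_and_none_is_zero(self):
        pm, table = self._fixture()
        assert pp.mass_fraction(table, "diatom", "none", 1, 3.0, pm).value \
            == pytest.approx(0.5)
        pm2 = pepmap_from_specs({"a": (("d",), ("ribosomal",))})
        t2 = simple_intensity_table([("a", 1, 3.0, 1, 3.0)])
        assert pp.mass_fraction(t2, "d", "ribosomal", 1, 3.0, pm2).value == 1.0
        assert pp.mass_fraction(t2, "d", "photosynthetic", 1, 3.0, pm2).value == 0.0

    def test_undefined_when_taxon_absent(self):
        pm, table = self._fixture()
        est = pp.mass_fraction(table, "haptophyte", "ribosomal", 1, 3.0, pm)
        assert not est.defined


class TestCombineAcrossFilters:
    def test_weighted_mean_example(self):
        combined = pp.combine_across_filters(
            {3.0: 0.2, 0.8: 0.4}, {3.0: 0.9, 0.8: 0.1})
        assert combined == pytest.approx(0.22)

    def test_identical_values_pass_through(self):
        assert pp.combine_across_filters(
            {3.0: 0.37, 0.8: 0.37, 0.1: 0.37},
            {3.0: 0.5, 0.8: 0.3, 0.1: 0.2}) == pytest.approx(0.37)

    def test_undefined_filters_renormalized(self):
        combined = pp.combine_across_filters(
            {3.0: 0.2, 0.8: None, 0.1: 0.4}, {3.0: 0.25, 0.8: 0.5, 0.1: 0.25})
        assert combined == pytest.approx(0.3)

    def test_all_undefined_returns_none(self):
        assert pp.combine_across_filters({3.0: None}, {3.0: 1.0}) is None

    @given(st.lists(
        st.tuples(st.floats(0, 1), st.floats(0.01, 1)), min_size=1, max_size=3))
    def test_convex_combination_bounds(self, pairs):
        estimates = {i: v for i, (v, _) in enumerate(pairs)}
        weights = {i: w for i, (_, w) in enumerate(pairs)}
        combined = pp.combine_across_filters(estimates, weights)
        values = list(estimates.values())
        assert min(values) - 1e-12 <= combined <= max(values) + 1e-12


class TestTaxonRelativeAbundance:
    def _fixture(self):
        pm = pepmap_from_specs({
            "a": (("t1",), ("none",)), "b": (("t2",), ("none",)),
            "c": (("t1",), ("none",)), "s": (("t1", "t2"), ("none",)),
        })
        rows = [("a", 1, 3.0, 1, 6.0), ("b", 1, 3.0, 1, 3.0),
                ("s", 1, 3.0, 1, 1.0),
                ("c", 1, 0.8, 1, 2.0), ("b", 1, 0.8, 1, 8.0)]
        return pm, simple_intensity_table(rows)

    def test_two_taxon_hand_computation(self):
        pm, table = self._fixture()
        mass = {3.0: 10.0, 0.8: 10.0, 0.1: 10.0}
        # shares: t1 = 0.6 on 3.0um (6/10), 0.2 on 0.8um; equal protein
        # mass so weights reduce to peptide counts 3/5 and 2/5
        value = pp.taxon_relative_abundance(table, "t1", 1, pm, mass)
        assert value == pytest.approx(0.6 * 0.6 + 0.2 * 0.4)
        # brute-force weighted sum for the second taxon
        t2 = pp.taxon_relative_abundance(table, "t2", 1, pm, mass)
        assert t2 == pytest.approx(0.3 * 0.6 + 0.8 * 0.4)

    def test_abundances_sum_below_one(self):
        pm, table = self._fixture()
        mass = {3.0: 5.0, 0.8: 15.0, 0.1: 1.0}
        total = sum(pp.taxon_relative_abundance(table, t, 1, pm, mass)
                    for t in ("t1", "t2"))
        assert total <= 1.0 + 1e-9

    def test_protein_mass_tilts_weights(self):
        pm, table = self._fixture()
        heavy_small = pp.taxon_relative_abundance(
            table, "t1", 1, pm, {3.0: 1.0, 0.8: 99.0, 0.1: 1.0})
        heavy_large = pp.taxon_relative_abundance(
            table, "t1", 1, pm, {3.0: 99.0, 0.8: 1.0, 0.1: 1.0})
        # t1 dominates the 3.0 um filter, so mass on 3.0 um raises it
        assert heavy_large > heavy_small

    def test_missing_mass_is_error(self):
        pm, table = self._fixture()
        with pytest.raises(QuantifyError):
            pp.taxon_relative_abundance(table, "t1", 1, pm, {3.0: 10.0})


class TestScaleInvariance:
    def test_injection_rescaling_cancels(self, small_dataset):
        ds = small_dataset
        table = ds.table.presence_filter()
        sample = table.samples()[0]
        scaled = table.rescale_injection(sample, 137.5)
        taxa = ds.truth.config.taxon_names
        base = pp.mass_fraction_table(table, ds.pepmap, taxa=taxa)
        other = pp.mass_fraction_table(scaled, ds.pepmap, taxa=taxa)
        a = base["value"].to_numpy(float)
        b = other["value"].to_numpy(float)
        mask = ~np.isnan(a)
        np.testing.assert_allclose(b[mask], a[mask], rtol=1e-12)
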