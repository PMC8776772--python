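"""DDA acquisition loop, feature generation and bias assessment."""
import numpy as np
import pandas as pd
import pytest

import protpool as pp
from protpool.cofrag import RTModel
from protpool.dda import DDAError, peptide_detectability, support_threshold


def make_features(specs, gradient=125.0, sigma=0.36):
    """specs: peptide -> (rt, intensity)."""
    frame = pd.DataFrame(
        {"rt": [rt for rt, _ in specs.values()],
         "sigma": sigma,
         "intensity": [i for _, i in specs.values()]},
        index=list(specs),
    )
    return pp.FeatureMap(frame=frame, gradient_length=gradient)


EXHAUSTIVE = pp.DDAParams(top_n=10**6, exclusion_duration=0.0,
                          detection_limit=0.0)


class TestDDAParams:
    def test_defaults_match_instrument_settings(self):
        params = pp.DDAParams()
        assert params.gradient_length == 125.0
        assert params.max_injection_time == pytest.approx(0.008333)
        assert params.isolation_window == 3.0
        assert params.peak_width == 1.44
        assert params.sparse_sampling_degree == 5
        assert params.elution_sigma == pytest.approx(0.36)

    def test_invalid_params_rejected(self):
        with pytest.raises(DDAError):
            pp.DDAParams(top_n=0)
        with pytest.raises(DDAError):
            pp.DDAParams(exclusion_duration=-1)


class TestSimulateDDARun:
    def test_exhaustive_sampling_identifies_everything(self):
        feats = make_features({"a": (10.0, 5.0), "b": (10.1, 1.0),
                               "c": (80.0, 2.0)})
        obs = pp.simulate_dda_run(feats, EXHAUSTIVE)
        assert obs.frame["identified"].all()
        assert obs.tic == pytest.approx(8.0)

    def test_empty_featuremap(self):
        feats = make_features({})
        obs = pp.simulate_dda_run(feats, EXHAUSTIVE)
        assert len(obs.frame) == 0 and obs.tic == 0.0

    def test_dynamic_exclusion_lets_weaker_coeluter_through(self):
        # two features at the same apex; with top_n=1 the brighter one wins
        # the apex cycle, and the dimmer is only reachable once the bright
        # one sits on the exclusion list
        specs = {"bright": (50.0, 10.0), "dim": (50.0, 5.0)}
        greedy = pp.DDAParams(top_n=1, exclusion_duration=0.0,
                              detection_limit=0.0)
        obs = pp.simulate_dda_run(make_features(specs), greedy)
        assert obs.frame.loc["bright", "identified"]
        assert not obs.frame.loc["dim", "identified"]
        excl = pp.DDAParams(top_n=1, exclusion_duration=200.0,
                            detection_limit=0.0)
        obs = pp.simulate_dda_run(make_features(specs), excl)
        assert obs.frame["identified"].all()

    def test_detection_limit_gates_dim_features(self):
        specs = {"bright": (30.0, 100.0), "dim": (90.0, 1.0)}
        params = pp.DDAParams(detection_limit=1.0)  # mean = 50.5
        obs = pp.simulate_dda_run(make_features(specs), params)
        assert obs.frame.loc["bright", "identified"]
        assert not obs.frame.loc["dim", "identified"]
        assert obs.tic == pytest.approx(101.0)  # TIC counts unidentified too

    def test_determinism(self):
        rng = np.random.default_rng(5)
        specs = {f"p{i}": (float(rng.uniform(0, 125)), float(rng.lognormal(0, 1)))
                 for i in range(200)}
        params = pp.DDAParams(top_n=3)
        a = pp.simulate_dda_run(make_features(specs), params)
        b = pp.simulate_dda_run(make_features(specs), params)
        assert a.frame.equals(b.frame)


class TestGenerateFeatures:
    def _community(self, **kwargs):
        config = pp.CommunityConfig(n_taxa=2, n_proteins_per_pool=4,
                                    n_timepoints=1, noise_cv=0.0,
                                    detectability_sd=0.0,
                                    shared_sequence_fraction=0.0,
                                    seed=17, **kwargs)
        proteins, truth = pp.simulate_community(config)
        pepmap = pp.build_peptide_map(proteins, compute_masses=False)
        return config, proteins, truth, pepmap

    def test_protein_mass_is_conserved_across_its_peptides(self):
        config, proteins, truth, pepmap = self._community()
        feats = pp.generate_features(pepmap, truth, 1, 3.0, pp.DDAParams())
        by_parent = {}
        for pep, row in pepmap.iterrows():
            if pep not in feats.frame.index:
                continue
            share = feats.frame.loc[pep, "intensity"] / len(row["parents"])
            for pid in row["parents"]:
                by_parent[pid] = by_parent.get(pid, 0.0) + share
        for pid, total in by_parent.items():
            expected = truth.abundance.loc[pid, 1] * config.retention(
                truth.proteins.loc[pid, "taxon"], 3.0)
            assert total == pytest.approx(expected, rel=1e-9)

    def test_zero_abundance_protein_absent(self):
        config, proteins, truth, pepmap = self._community()
        pid = truth.proteins.index[0]
        truth.abundance.loc[pid, 1] = 0.0
        feats = pp.generate_features(pepmap, truth, 1, 3.0, pp.DDAParams())
        only_mine = pepmap["parents"].map(lambda ps: ps == (pid,))
        assert not set(pepmap.index[only_mine]) & set(feats.frame.index)

    def test_shared_peptide_sums_both_parents(self):
        proteins = [
            pp.ProteinRecord("p1", "t1", "AAAGGGTTTKCCCDDDR"),
            pp.ProteinRecord("p2", "t1", "AAAGGGTTTKEEEFFFR"),
        ]
        pepmap = pp.build_peptide_map(proteins, missed_cleavages=0,
                                      compute_masses=False)
        config = pp.CommunityConfig(n_taxa=1, n_proteins_per_pool=1,
                                    n_timepoints=1, noise_cv=0.0,
                                    detectability_sd=0.0, seed=0)
        abundance = pd.DataFrame({1: [3.0, 5.0]}, index=["p1", "p2"])
        prot_frame = pd.DataFrame(
            {"taxon": ["taxon1", "taxon1"], "pool": ["other", "other"],
             "env_dependent": [False, False]}, index=["p1", "p2"])
        truth = pp.TruthTable(proteins=prot_frame, abundance=abundance,
                              config=config)
        feats = pp.generate_features(pepmap, truth, 1, 3.0, pp.DDAParams())
        ret = config.retention("taxon1", 3.0)
        # each protein has 2 mapped peptides; the shared one gets half of each
        assert feats.frame.loc["AAAGGGTTTK", "intensity"] == pytest.approx(
            (3.0 / 2 + 5.0 / 2) * ret)
        assert feats.frame.loc["CCCDDDR", "intensity"] == pytest.approx(
            3.0 / 2 * ret)

    def test_unknown_parent_is_error(self):
        config, proteins, truth, pepmap = self._community()
        bad = pepmap.copy()
        bad.loc[bad.index[0], "parents"] = ("ghost",)
        with pytest.raises(DDAError, match="ghost"):
            pp.generate_features(bad, truth, 1, 3.0, pp.DDAParams())

    def test_detectability_is_stable_across_calls(self, small_dataset):
        pm = small_dataset.pepmap
        a = peptide_detectability(pm, 1.0, 123)
        b = peptide_detectability(pm, 1.0, 123)
        assert a.equals(b)
        assert abs(a.mean() - 1.0) < 0.1


class TestAssessBias:
    def test_exhaustive_noise_free_is_oracle_exact(self):
        config = pp.CommunityConfig(n_taxa=3, n_proteins_per_pool=8,
                                    n_timepoints=1, noise_cv=0.0,
                                    detectability_sd=0.0,
                                    shared_sequence_fraction=0.0, seed=31)
        proteins, truth = pp.simulate_community(config)
        pepmap = pp.build_peptide_map(proteins, compute_masses=False)
        feats = pp.generate_features(pepmap, truth, 1, 3.0, EXHAUSTIVE)
        obs = pp.simulate_dda_run(feats, EXHAUSTIVE)
        bias = pp.assess_bias(obs, truth, pepmap, 1, 3.0)
        assert bias["bias_fraction"].abs().max() < 1e-9
        assert bias["bias_share"].abs().max() < 1e-9

    def test_heavy_sharing_underestimates_community_share(self):
        # near-identical taxa lose their taxon-unique peptides, so the
        # share of total signal attributed to them falls short
        config = pp.CommunityConfig(n_taxa=2, n_proteins_per_pool=15,
                                    n_timepoints=1, noise_cv=0.0,
                                    shared_sequence_fraction=0.8, seed=13)
        proteins, truth = pp.simulate_community(config)
        pepmap = pp.build_peptide_map(proteins, compute_masses=False)
        feats = pp.generate_features(pepmap, truth, 1, 3.0, EXHAUSTIVE)
        obs = pp.simulate_dda_run(feats, EXHAUSTIVE)
        bias = pp.assess_bias(obs, truth, pepmap, 1, 3.0)
        per_taxon = bias.groupby("taxon")["bias_share"].sum()
        assert (per_taxon < 0).all()


class TestSupportThreshold:
    def _frame(self, counts, biases):
        return pd.DataFrame({"n_unique_identified": counts,
                             "rel_bias_fraction": biases})

    def test_clean_step_function(self):
        counts = [5] * 10 + [60] * 10 + [300] * 10
        biases = [-0.5] * 10 + [0.01] * 10 + [-0.002] * 10
        assert support_threshold(self._frame(counts, biases)) == 50

    def test_unbiased_everywhere_gives_zero(self):
        counts = [5] * 10 + [500] * 10
        biases = [0.0] * 20
        assert support_threshold(self._frame(counts, biases)) == 0

    def test_biased_top_bin_gives_none(self):
        counts = [500] * 10
        biases = [-0.4] * 10
        assert support_threshold(self._frame(counts, biases)) is None

    def test_sparse_bins_contribute_no_evidence(self):
        # 2 grains < min_bin: the (25, 50] bin neither passes nor blocks,
        # so the threshold stays at the lowest populated passing edge
        counts = [30] * 2 + [300] * 10
        biases = [-0.9] * 2 + [0.0] * 10
        assert support_threshold(self._frame(counts, biases)) == 200
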