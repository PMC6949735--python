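"""Synthetic-data generators: determinism, marginals, planted structure."""

import math

import numpy as np
import pytest

from herbnet.adme import ScreeningCriteria, screen
from herbnet.errors import ConfigError
from herbnet.simulate import (Dist, SimulationConfig, expected_pass_rate,
                              gen_annotations, gen_catalogue,
                              gen_likelihood_matrix, write_simulated_inputs)
from herbnet.enrich import TermUniverse, hypergeom_enrich
from herbnet.targets import dedupe_targets, threshold_pairs


class TestConfigValidation:
    def test_negative_herb_count_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(herbs=(("a", -1),))

    def test_hub_index_out_of_range(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_compounds=5, hub_compounds=((7, 3),))

    def test_overlapping_hub_spec_rejected(self):
        with pytest.raises(ConfigError, match="overlapping"):
            SimulationConfig(hub_compounds=((0, 5), (0, 7)))

    def test_nonpositive_odds_rejected(self):
        with pytest.raises(ConfigError, match="odds"):
            SimulationConfig(planted_terms=((0, 0.0),))


class TestCatalogue:
    def test_default_counts_382_total(self):
        cat = gen_catalogue(SimulationConfig(seed=1))
        assert len(cat) == 382
        per_herb = {}
        for r in cat:
            per_herb[r.herb] = per_herb.get(r.herb, 0) + 1
        assert sorted(per_herb.values(), reverse=True) == [190, 87, 57, 48]

    def test_zero_ingredients_empty(self):
        cat = gen_catalogue(SimulationConfig(herbs=(("a", 0), ("b", 0))))
        assert cat == []

    def test_point_masses_all_pass_default_screen(self):
        cfg = SimulationConfig(
            seed=2,
            ob_dist=Dist("point", {"value": 50.0}),
            dl_dist=Dist("point", {"value": 0.5}),
            hl_dist=Dist("point", {"value": 6.0}))
        report = screen(gen_catalogue(cfg))
        assert report.n_pass == report.n_total == 382
        assert expected_pass_rate(cfg) == 1.0

    def test_determinism_and_substream_independence(self):
        a = gen_catalogue(SimulationConfig(seed=5))
        b = gen_catalogue(SimulationConfig(seed=5))
        assert a == b
        # a different seed must actually change the draws
        c = gen_catalogue(SimulationConfig(seed=6))
        assert a != c

    def test_empirical_pass_rate_within_3_se_of_closed_form(self):
        # pool several seeds for a tight binomial check of the marginals
        cfg0 = SimulationConfig()
        rate = expected_pass_rate(cfg0)
        n_pass = n_tot = 0
        for seed in range(10):
            rep = screen(gen_catalogue(SimulationConfig(seed=seed)))
            n_pass += rep.n_pass
            n_tot += rep.n_total
        se = math.sqrt(rate * (1 - rate) / n_tot)
        assert abs(n_pass / n_tot - rate) <= 3 * se

    def test_default_design_retains_about_one_in_ten(self):
        # the documented stylistic calibration of the default marginals
        assert 0.08 <= expected_pass_rate(SimulationConfig()) <= 0.12


class TestLikelihoodMatrix:
    def test_dimensions_and_determinism(self):
        cfg = SimulationConfig(seed=3)
        a = gen_likelihood_matrix(cfg)
        b = gen_likelihood_matrix(cfg)
        assert a.pairs == b.pairs
        assert len(a.pairs) == cfg.n_compounds * cfg.n_targets

    def test_hub_compound_degree_within_binomial_error(self):
        # accepted degree of a hub ~ Binomial(73, P(true >= 7)) plus
        # background acceptances ~ Binomial(n_targets - 73, P(bg >= 7))
        cfg0 = SimulationConfig()
        p_true = cfg0.true_dist.prob_ge(7.0)
        p_bg = cfg0.background_dist.prob_ge(7.0)
        hub_total = 0
        reps = 50
        for seed in range(reps):
            sim = gen_likelihood_matrix(SimulationConfig(seed=seed))
            acc = dedupe_targets(threshold_pairs(sim.pairs))
            hub_total += acc.compound_degree.get("C000", 0)
        expect = 73 * p_true + (94 - 73) * p_bg
        var = (73 * p_true * (1 - p_true) + 21 * p_bg * (1 - p_bg)) / reps
        assert abs(hub_total / reps - expect) <= 3 * math.sqrt(var)

    def test_threshold_infinity_accepts_nothing(self):
        sim = gen_likelihood_matrix(SimulationConfig(seed=4))
        assert threshold_pairs(sim.pairs, float("inf")) == []

    def test_true_pairs_recorded_for_hubs(self):
        cfg = SimulationConfig(seed=8, hub_compounds=((0, 73),),
                               baseline_targets_per_compound=5)
        sim = gen_likelihood_matrix(cfg)
        assert sum(1 for c, _ in sim.true_pairs if c == "C000") == 73


class TestAnnotations:
    def test_zero_terms_empty_table(self):
        df, truth = gen_annotations(SimulationConfig(seed=1, n_terms=0))
        assert len(df) == 0 and truth.planted == {}

    def test_determinism(self):
        a, _ = gen_annotations(SimulationConfig(seed=9))
        b, _ = gen_annotations(SimulationConfig(seed=9))
        assert a.equals(b)

    def test_null_odds_type_i_rate_calibrated(self):
        # odds = 1 everywhere: across replicates the fraction of terms with
        # p < 0.05 must not exceed 0.05 + 3 SE (discreteness makes it lower)
        alpha, n_sig, n_terms = 0.05, 0, 0
        for seed in range(300):
            cfg = SimulationConfig(seed=seed, n_terms=10)
            df, truth = gen_annotations(cfg)
            if len(df) == 0:
                continue
            universe = TermUniverse.from_annotation_table(
                df, background=cfg.target_ids())
            res = hypergeom_enrich(truth.query, universe, alpha=alpha)
            n_sig += sum(1 for r in res.results if r.p_value < alpha)
            n_terms += len(res.results)
        rate = n_sig / n_terms
        se = math.sqrt(alpha * (1 - alpha) / n_terms)
        assert rate <= alpha + 3 * se

    def test_planted_term_attains_smallest_p(self):
        hits = 0
        reps = 100
        for seed in range(reps):
            cfg = SimulationConfig(seed=seed, n_terms=20,
                                   planted_terms=((7, 20.0),))
            df, truth = gen_annotations(cfg)
            universe = TermUniverse.from_annotation_table(
                df, background=cfg.target_ids())
            res = hypergeom_enrich(truth.query, universe)
            if res.results[0].term_id == "term007":
                hits += 1
        assert hits / reps >= 0.95


class TestFileEmission:
    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=11, herbs=(("a", 20), ("b", 10)),
                               n_compounds=5, n_targets=10,
                               hub_compounds=((0, 8),), n_terms=5,
                               query_size=5)
        p1 = write_simulated_inputs(cfg, tmp_path / "run1")
        p2 = write_simulated_inputs(cfg, tmp_path / "run2")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()
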