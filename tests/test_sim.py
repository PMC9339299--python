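"""Forward meiosis simulator: chiasma process, resolution, event models."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from tetrads import (
    MarkerMap,
    SimulationConfig,
    apply_gene_conversion,
    apply_missegregation_and_death,
    chiasma_count_model,
    count_gene_conversions,
    draw_meiosis_trace,
    infer_mi_ndj,
    resolve_tetrad,
    score_marker_segregation,
    simulate_experiment,
    tabulate_interval_counts,
    viability_table,
)
from tetrads.datasets import WT_INTERVAL_CM, reference_marker_map
from tetrads.model import PD, TT, classify_interval
from tetrads.sim import ChromosomeTrace, MeiosisTrace, calibrate_interval_length, perkins_expectation


def _pair_config(cm=35.0, **kw):
    mmap = MarkerMap.from_pairs([("A", "1"), ("B", "1")])
    defaults = dict(
        marker_map=mmap, interval_cm={("A", "B"): cm}, n_tetrads=10, seed=0,
        interference_m=0, gene_conversion_prob=0.0, spore_death_prob=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestChiasmaProcess:
    def test_zero_length_no_chiasmata(self):
        rng = np.random.default_rng(0)
        assert chiasma_count_model(0.0, 0, rng).size == 0
        assert chiasma_count_model(0.0, 5, rng).size == 0

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            chiasma_count_model(-0.1, 0, np.random.default_rng(0))

    def test_poisson_mean_two_per_morgan(self):
        rng = np.random.default_rng(5)
        x, reps = 0.284, 100_000
        counts = np.array([chiasma_count_model(x, 0, rng).size for _ in range(reps)])
        se = counts.std() / np.sqrt(reps)
        assert counts.mean() == pytest.approx(2 * x, abs=3 * se)

    def test_counting_model_keeps_density_and_reduces_variance(self):
        rng = np.random.default_rng(6)
        x, reps, m = 0.5, 40_000, 4
        counts = np.array([chiasma_count_model(x, m, rng).size for _ in range(reps)])
        se = counts.std() / np.sqrt(reps)
        assert counts.mean() == pytest.approx(2 * x, abs=3 * se)  # stationarity
        assert counts.var() < counts.mean()  # underdispersed vs Poisson


class TestResolution:
    def _resolve_with(self, config, chiasmata, rng=None):
        rng = rng or np.random.default_rng(0)
        trace = MeiosisTrace(
            (ChromosomeTrace("1", chiasmata, int(rng.integers(2)), ((0, 1), (0, 1))),)
        )
        return resolve_tetrad(trace, config)

    def test_no_chiasma_is_parental_ditype(self):
        tet = self._resolve_with(_pair_config(), ())
        assert classify_interval(tet, "A", "B") == PD

    def test_single_chiasma_is_tetratype(self):
        cfg = _pair_config()
        for picks in ((0, 0), (0, 1), (1, 0), (1, 1)):
            tet = self._resolve_with(cfg, ((0.1, *picks),))
            assert classify_interval(tet, "A", "B") == TT

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_tetratype_probability_given_k_chiasmata(self, k):
        # closed form under no chromatid interference:
        # P(TT | k) = (2/3) (1 - (-1/2)^k)
        cfg = _pair_config()
        rng = np.random.default_rng(10 + k)
        reps = 20_000
        hits = 0
        for _ in range(reps):
            chiasmata = tuple(
                (0.05 + 0.01 * i, int(rng.integers(2)), int(rng.integers(2)))
                for i in range(k)
            )
            tet = self._resolve_with(cfg, chiasmata, rng)
            hits += classify_interval(tet, "A", "B") == TT
        expected = (2 / 3) * (1 - (-0.5) ** k)
        se = np.sqrt(max(expected * (1 - expected), 0.25 / reps) / reps)
        assert hits / reps == pytest.approx(expected, abs=3.5 * se)

    def test_allele_conservation_before_death(self):
        # every marker is 2:2 across spores unless a conversion touched it
        mmap = reference_marker_map()
        cfg = SimulationConfig(
            marker_map=mmap, interval_cm=WT_INTERVAL_CM, n_tetrads=200, seed=11,
            interference_m=0, gene_conversion_prob=0.0, spore_death_prob=0.0,
        )
        for tet in simulate_experiment(cfg):
            for marker in mmap.marker_names:
                assert score_marker_segregation(tet, marker) == "2:2"


class TestGeneConversionStage:
    def test_zero_rate_is_identity(self):
        cfg = _pair_config()
        rng = np.random.default_rng(0)
        tet = resolve_tetrad(draw_meiosis_trace(cfg, rng), cfg)
        assert apply_gene_conversion(tet, 0.0, rng, cfg) == tet

    def test_rate_one_converts_everything(self):
        cfg = _pair_config()
        rng = np.random.default_rng(1)
        tet = resolve_tetrad(draw_meiosis_trace(cfg, rng), cfg)
        converted = apply_gene_conversion(tet, 1.0, rng, cfg)
        for marker in cfg.marker_map.marker_names:
            assert score_marker_segregation(converted, marker) != "2:2"

    def test_mean_conversions_match_nine_g(self):
        # g = 0.015 over 9 markers: 0.135 expected conversions per tetrad,
        # the wild-type calibration
        mmap = reference_marker_map()
        cfg = SimulationConfig(
            marker_map=mmap, interval_cm=WT_INTERVAL_CM, n_tetrads=500, seed=12,
            interference_m=0, gene_conversion_prob=0.015, spore_death_prob=0.0,
        )
        counts = [count_gene_conversions(t, mmap) for t in simulate_experiment(cfg)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(0.135, abs=3 * se)


class TestMissegregationAndDeath:
    def test_all_rates_zero_keeps_four_viable(self):
        cfg = _pair_config()
        rng = np.random.default_rng(0)
        tet = resolve_tetrad(draw_meiosis_trace(cfg, rng), cfg)
        assert apply_missegregation_and_death(tet, cfg, rng).n_viable == 4

    def test_mi_ndj_two_viable_nonmaters(self):
        # MAT at the centromere: disomic survivors always carry both alleles
        mmap = MarkerMap.from_pairs(
            [("MAT", "III"), ("B", "III")], centromere_index={"III": 0.0}
        )
        cfg = SimulationConfig(
            marker_map=mmap, interval_cm={("MAT", "B"): 30.0}, n_tetrads=2000,
            seed=13, interference_m=0, gene_conversion_prob=0.0,
            spore_death_prob=0.0, mi_ndj_prob=0.06,
        )
        tets = simulate_experiment(cfg)
        table = viability_table(tets)
        assert table.classes[1] == 0  # MI NDJ never yields 3-spore-viable
        for tet in tets:
            if tet.n_viable == 2:
                assert [s.mating for s in tet.viable_spores] == ["non", "non"]
        res = infer_mi_ndj(tets)
        rate = res.events / len(tets)
        se = np.sqrt(0.06 * 0.94 / len(tets))
        assert rate == pytest.approx(0.06, abs=2 * se)

    def test_mii_pssc_enriches_three_viable(self):
        cfg = _pair_config(n_tetrads=2000, seed=14, mii_pssc_prob=0.1)
        classes = viability_table(simulate_experiment(cfg)).classes
        frac3 = classes[1] / 2000
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert frac3 == pytest.approx(0.1, abs=3 * se)  # one PSSC kills one spore
        assert classes[2] == 0

    def test_dead_spores_are_blanked(self):
        cfg = _pair_config(n_tetrads=300, seed=15, spore_death_prob=0.3)
        for tet in simulate_experiment(cfg):
            for spore in tet.spores:
                if not spore.viable:
                    assert set(spore.alleles.values()) == {"-"}


class TestExperiment:
    def test_same_seed_identical_output(self, tmp_path):
        from tetrads.io import write_tetrad_table

        mmap = reference_marker_map()
        paths = []
        for i in range(2):
            cfg = SimulationConfig(
                marker_map=mmap, interval_cm=WT_INTERVAL_CM, n_tetrads=50, seed=77,
                mi_ndj_prob=0.01, mii_pssc_prob=0.02, spore_death_prob=0.05,
            )
            path = tmp_path / f"run{i}.tsv"
            write_tetrad_table(path, simulate_experiment(cfg), mmap)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        out = [
            simulate_experiment(_pair_config(n_tetrads=30, seed=s)) for s in (1, 2)
        ]
        assert out[0] != out[1]

    def test_strong_interference_suppresses_npd_across_seeds(self):
        # 28.4 cM interval, m = 10: observed NPD under half the
        # no-interference expectation in nearly every replicate
        hits = 0
        for seed in range(20):
            cfg = _pair_config(cm=28.4, n_tetrads=1000, seed=seed, interference_m=10)
            counts = tabulate_interval_counts(simulate_experiment(cfg), cfg.marker_map)[0]
            n = counts.n
            f_t = counts.tt / n
            expected = n * 0.5 * (1 - f_t - np.cbrt(1 - 1.5 * f_t) ** 2)
            hits += expected > 0 and counts.npd < 0.5 * expected
        assert hits >= 19

    def test_calibration_inverts_perkins_expectation(self):
        for d, m in ((0.284, 0), (0.416, 0), (0.35, 4)):
            x = calibrate_interval_length(d, m)
            assert perkins_expectation(x, m) == pytest.approx(d, abs=1e-6)
            assert x >= d  # attenuation always stretches the raw line

    def test_round_trip_recovers_configured_rates(self):
        # full-feature run: viability, NDJ and conversion rates all recovered
        mmap = reference_marker_map()
        n = 3000
        cfg = SimulationConfig(
            marker_map=mmap, interval_cm=WT_INTERVAL_CM, n_tetrads=n, seed=16,
            interference_m=0, gene_conversion_prob=0.015,
            mi_ndj_prob={"III": 0.03}, spore_death_prob=0.02,
        )
        tets = simulate_experiment(cfg)
        table = viability_table(tets)
        # expected viability: MI NDJ kills 2 spores in 3% of meioses, then
        # 2% random death: (1 - 0.03/2) * 0.98
        expected_viability = 100 * (1 - 0.015) * 0.98
        assert table.percent_viability == pytest.approx(expected_viability, abs=1.0)
        ndj = infer_mi_ndj(tets)
        se = np.sqrt(0.03 * 0.97 / n)
        # survivors of an NDJ meiosis may still die randomly, so compare
        # double-nonmater tetrads against meioses with both survivors alive
        expected_events = 0.03 * 0.98**2
        assert ndj.events / n == pytest.approx(expected_events, abs=2.5 * se)
        four = [t for t in tets if t.n_viable == 4]
        gcs = [count_gene_conversions(t, mmap) for t in four]
        se_gc = np.std(gcs) / np.sqrt(len(gcs))
        assert np.mean(gcs) == pytest.approx(0.135, abs=3 * se_gc)


class TestConfigValidation:
    def test_missing_interval_distance(self):
        mmap = MarkerMap.from_pairs([("A", "1"), ("B", "1")])
        with pytest.raises(ValueError, match="no true distance"):
            SimulationConfig(
                marker_map=mmap, interval_cm={}, n_tetrads=5, seed=0
            )

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            _pair_config(gene_conversion_prob=1.5)
        with pytest.raises(ValueError):
            _pair_config(mi_ndj_prob=-0.1)
        with pytest.raises(ValueError):
            _pair_config(interference_m=-1)
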