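"""Backtracking index, z-scoring, Rpb4/Rpb3 ratio profiles, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from imprintseq import synthetic_data as sd
from imprintseq.backtracking_stoich import (
    backtracking_index,
    body_ratio,
    correlation_ledger,
    gene_end_averages,
    ratio_profile,
    zscore_mad,
    zscore_median,
)
from imprintseq.core_io import GeneAnnotation, SignalTrack


@pytest.fixture(scope="module")
def backtrack_sim():
    sim = sd.generate_genome(n_genes=200, length_range=(800, 2000), seed=80)
    sd.plant_crac_track(sim, seed=81)
    tracks = sd.generate_chip_gro(sim, seed=82)
    return sim, tracks


class TestGeneEndAverages:
    def test_constant_track(self):
        track = SignalTrack({"c": 2000})
        track.values("c", "+")[:] = 3.0
        g = GeneAnnotation("g", "c", "+", 100, 1100)
        out = gene_end_averages(track, [g])
        assert out.loc["g", "mean5"] == pytest.approx(3.0)
        assert out.loc["g", "mean3"] == pytest.approx(3.0)

    def test_linear_ramp_arithmetic_series(self):
        """Ramp 0..L-1 over a 1000 bp gene: tile means 124.5 and 874.5."""
        track = SignalTrack({"c": 2000})
        g = GeneAnnotation("g", "c", "+", 100, 1100)
        track.values("c", "+")[100:1100] = np.arange(1000, dtype=float)
        out = gene_end_averages(track, [g])
        assert out.loc["g", "mean5"] == pytest.approx(124.5)
        assert out.loc["g", "mean3"] == pytest.approx(874.5)

    def test_minus_strand_ramp(self):
        """The 5' tile of a - strand gene sits at the high-coordinate end."""
        track = SignalTrack({"c": 2000})
        g = GeneAnnotation("g", "c", "-", 1100, 100)
        track.values("c", "-")[100:1100] = np.arange(1000, dtype=float)
        out = gene_end_averages(track, [g])
        assert out.loc["g", "mean5"] == pytest.approx(874.5)
        assert out.loc["g", "mean3"] == pytest.approx(124.5)

    def test_short_gene_clipped_and_flagged(self):
        track = SignalTrack({"c": 1000})
        track.values("c", "+")[:] = 2.0
        g = GeneAnnotation("g", "c", "+", 100, 300)
        out = gene_end_averages(track, [g])
        assert out.loc["g", "clipped"]
        assert out.loc["g", "mean5"] == out.loc["g", "mean3"] == pytest.approx(2.0)


class TestBacktrackingIndex:
    def _means(self, vals):
        return pd.DataFrame({"mean5": vals, "mean3": vals}, index=[f"g{i}" for i in range(len(vals))])

    def test_simple_ratio(self):
        out = backtracking_index(self._means([4.0]), self._means([2.0]))
        assert out.loc["g0", "BI"] == pytest.approx(2.0)

    def test_equal_signals_unity(self):
        out = backtracking_index(self._means([3.0, 5.0]), self._means([3.0, 5.0]))
        np.testing.assert_allclose(out["BI"], 1.0)

    def test_zero_gro_flagged(self):
        out = backtracking_index(self._means([4.0]), self._means([0.0]))
        assert not out.loc["g0", "bi_defined"]
        assert np.isnan(out.loc["g0", "BI"])

    def test_noiseless_generator_bi_tracks_planted_b(self, backtrack_sim):
        """BI is proportional to 1/(1-b): Spearman rho = 1 in the noiseless sim."""
        sim, tracks = backtrack_sim
        chip, gro = tracks["WT"]
        bi = backtracking_index(
            gene_end_averages(chip, sim.annotations), gene_end_averages(gro, sim.annotations)
        )["BI"]
        b = sim.truth["backtrack_b"]
        assert spearmanr(bi, 1 / (1 - b)).statistic == pytest.approx(1.0)
        assert spearmanr(bi, b).statistic == pytest.approx(1.0)
        np.testing.assert_allclose(bi, 1 / (1 - b), rtol=1e-9)

    def test_bi_scale_invariance(self, backtrack_sim):
        sim, tracks = backtrack_sim
        chip, gro = tracks["WT"]
        genes = sim.annotations[:30]
        base = backtracking_index(gene_end_averages(chip, genes), gene_end_averages(gro, genes))["BI"]
        both = backtracking_index(
            gene_end_averages(chip.scaled(3.0), genes), gene_end_averages(gro.scaled(3.0), genes)
        )["BI"]
        chip_only = backtracking_index(
            gene_end_averages(chip.scaled(3.0), genes), gene_end_averages(gro, genes)
        )["BI"]
        np.testing.assert_allclose(both, base, rtol=1e-12)
        np.testing.assert_allclose(chip_only, 3.0 * base, rtol=1e-12)


class TestZscoreMedian:
    def test_hand_case(self):
        np.testing.assert_allclose(zscore_median([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_median_zero_sd_one(self):
        rng = np.random.default_rng(10)
        z = zscore_median(rng.lognormal(1, 0.8, 501))
        assert np.median(z) == pytest.approx(0.0, abs=1e-14)
        assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(3, 2, 100)
        np.testing.assert_allclose(zscore_median(5 + 2.5 * x), zscore_median(x), rtol=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            zscore_median([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            zscore_mad([1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def rpb4_sim():
    sim = sd.generate_genome(n_genes=120, length_range=(800, 2000), seed=85)
    sd.plant_crac_track(sim, seed=86)
    slopes = pd.Series(
        [0.5 * 1000 / a.length for a in sim.annotations],
        index=[a.gene_id for a in sim.annotations],
    )
    rpb4, rpb3 = sd.generate_rpb4_tracks(sim, slopes, seed=87)
    return sim, rpb4, rpb3


class TestRatioProfile:
    def test_equal_tracks_flat_unity(self):
        sim = sd.generate_genome(n_genes=30, seed=88)
        sd.plant_crac_track(sim, seed=89)
        rpb4, rpb3 = sd.generate_rpb4_tracks(sim, 0.0, seed=90)
        prof = ratio_profile(rpb4, rpb3, sim.annotations)
        np.testing.assert_allclose(prof.tss_ratio, 1.0, atol=1e-12)
        np.testing.assert_allclose(prof.pa_ratio, 1.0, atol=1e-12)

    def test_planted_decline_endpoint_and_anchor(self, rpb4_sim):
        """Decline to 0.5 at pA: profile endpoint 0.5 +/- 1e-9, TSS -100 exactly 1."""
        sim, rpb4, rpb3 = rpb4_sim
        prof = ratio_profile(rpb4, rpb3, sim.annotations)
        assert prof.tss_ratio[prof.tss_offsets == -100][0] == pytest.approx(1.0, abs=1e-12)
        assert prof.pa_ratio[-1] == pytest.approx(0.5, abs=1e-9)
        assert prof.pa_ratio[prof.pa_offsets == 0][0] == pytest.approx(0.5, abs=1e-9)

    def test_zero_slope_condition_distinguishable(self, rpb4_sim):
        sim, rpb4, rpb3 = rpb4_sim
        # fresh simulation for the flat (mutant-like) condition, so the
        # shared fixture's truth table is untouched
        sim_flat = sd.generate_genome(n_genes=120, length_range=(800, 2000), seed=85)
        sd.plant_crac_track(sim_flat, seed=86)
        flat4, flat3 = sd.generate_rpb4_tracks(sim_flat, 0.0, seed=91)
        declining = ratio_profile(rpb4, rpb3, sim.annotations)
        flat = ratio_profile(flat4, flat3, sim_flat.annotations)
        full_decl = np.concatenate([declining.tss_ratio, declining.pa_ratio])
        full_flat = np.concatenate([flat.tss_ratio, flat.pa_ratio])
        gap_decl = np.nanmax(full_decl) - np.nanmin(full_decl)
        gap_flat = np.nanmax(full_flat) - np.nanmin(full_flat)
        assert gap_decl > 0.3 and gap_flat < 1e-9


class TestBodyRatio:
    def test_constant_double(self):
        track3 = SignalTrack({"c": 2000})
        track3.values("c", "+")[:] = 2.0
        track4 = track3.scaled(2.0)
        g = GeneAnnotation("g", "c", "+", 100, 1100)
        assert body_ratio(track4, track3, [g])["g"] == pytest.approx(2.0)

    def test_planted_slope_closed_form(self, rpb4_sim):
        """Mean ratio over TSS..+250 and -250..pA matches the arithmetic mean
        of the planted linear decline over those windows."""
        sim, rpb4, rpb3 = rpb4_sim
        out = body_ratio(rpb4, rpb3, sim.annotations)
        for ann in sim.annotations[:25]:
            s = sim.truth.loc[ann.gene_id, "rpb4_slope_per_kb"] / 1000.0
            L = ann.length
            d = np.concatenate([np.arange(0, 250), np.arange(L - 250, L)])
            expected = np.mean(1.0 - s * d)
            assert out[ann.gene_id] == pytest.approx(expected, abs=1e-9)

    def test_matches_loop_oracle_on_random_tracks(self):
        rng = np.random.default_rng(13)
        sizes = {"c": 3000}
        t4, t3 = SignalTrack(sizes), SignalTrack(sizes)
        t4.values("c", "+")[:] = rng.uniform(0.5, 2.0, 3000)
        t3.values("c", "+")[:] = rng.uniform(0.5, 2.0, 3000)
        g = GeneAnnotation("g", "c", "+", 400, 1400)
        out = body_ratio(t4, t3, [g])["g"]
        v4, v3 = t4.values("c", "+"), t3.values("c", "+")
        ratios = [v4[i] / v3[i] for i in list(range(400, 650)) + list(range(1150, 1400))]
        assert abs(out - np.mean(ratios)) < 1e-12


class TestCorrelationLedger:
    def test_perfect_linear_pair(self):
        df = pd.DataFrame({"x": np.arange(10.0)}, index=[f"g{i}" for i in range(10)])
        df["y"] = 2 * df["x"]
        led = correlation_ledger(df, [("x", "y")], {"all": df.index})
        r = led.set_index("method")["r"]
        assert r["pearson"] == pytest.approx(1.0)
        assert r["spearman"] == pytest.approx(1.0)

    def test_permuted_pair_near_zero(self):
        rng = np.random.default_rng(14)
        rs = []
        for _ in range(100):
            x = np.arange(100.0)
            df = pd.DataFrame({"x": x, "y": rng.permutation(x)}, index=[f"g{i}" for i in range(100)])
            led = correlation_ledger(df, [("x", "y")], {"all": df.index})
            rs.append(led[led["method"] == "spearman"]["r"].iloc[0])
        assert np.mean(np.abs(rs) < 3 / np.sqrt(100)) > 0.95

    def test_coupled_simulation_crac_correlation_exceeds_rest(self):
        """When b drives both BI and HL suppression in CRAC+ genes only, the
        BI_ratio ~ HL_ratio correlation is higher in CRAC+ than in the rest."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 150
            is_pos = np.arange(n) < 60
            b = np.where(is_pos, rng.uniform(0.3, 0.7, n), rng.uniform(0.05, 0.4, n))
            b_mut = np.where(is_pos, b / 2, b)
            bi_ratio = ((1 / (1 - b_mut)) / (1 / (1 - b))) * rng.lognormal(0, 0.05, n)
            hl_ratio = np.where(is_pos, (1 - b) / (1 - b_mut), 1.0) * rng.lognormal(0, 0.05, n)
            df = pd.DataFrame(
                {"BI_ratio": bi_ratio, "HL_ratio": hl_ratio},
                index=[f"g{i}" for i in range(n)],
            )
            sets = {"CRAC+": df.index[is_pos], "rest": df.index[~is_pos]}
            led = correlation_ledger(df, [("BI_ratio", "HL_ratio")], sets)
            p = led[led["method"] == "pearson"].set_index("gene_set")["r"]
            wins += p["CRAC+"] > p["rest"]
        assert wins >= 95
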