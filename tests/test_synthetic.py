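"""Synthetic-data generators: determinism, closed forms, pipeline recovery."""

import numpy as np
import pytest

from phagepst import errors
from phagepst.cocktail import optimize_cocktail
from phagepst.io_tables import LYSIS, NO_LYSIS
from phagepst.mrgn import classify_mrgn
from phagepst.pka import pka_matrix, pka_table
from phagepst.synthetic import (GrowthParams, LysisParams, example_breakpoints,
                                infected_od, logistic_od, lysis_onset,
                                simulate_antibiogram, simulate_control_curve,
                                simulate_host_range, simulate_infected_curve,
                                simulate_moi_series, simulate_pka_plate)
from phagepst.virulence import global_virulence


class TestControlCurve:
    def test_noise_free_starts_at_inoculum(self):
        c = simulate_control_curve(GrowthParams(), seed=0)
        assert c.od[0] == pytest.approx(0.1)

    def test_fast_growth_reaches_capacity(self):
        g = GrowthParams(r=3.0)
        c = simulate_control_curve(g, seed=0)
        assert c.od[-1] == pytest.approx(g.K, abs=1e-6 * g.K)

    def test_seed_determinism(self):
        g = GrowthParams(noise_sd=0.05)
        a = simulate_control_curve(g, seed=42)
        b = simulate_control_curve(g, seed=42)
        np.testing.assert_array_equal(a.od, b.od)
        c = simulate_control_curve(g, seed=43)
        assert not np.array_equal(a.od, c.od)

    def test_invalid_params_rejected(self):
        with pytest.raises(errors.ValidationError):
            GrowthParams(od0=0.5, K=0.4)


class TestInfectedCurve:
    def test_total_kill_limit(self):
        g = GrowthParams()
        l = LysisParams(t0=2.0, tau=0.0, lam=1e9, floor=0.0)
        c = simulate_infected_curve(g, l, moi=1.0, seed=0)
        after = c.times > 2.0
        np.testing.assert_allclose(c.od[after], 0.0, atol=1e-12)

    def test_moi_shifts_onset_by_tau_per_decade(self):
        l = LysisParams(t0=6.0, tau=1.0)
        assert lysis_onset(l, 1.0) == pytest.approx(6.0)
        assert lysis_onset(l, 0.0001) - lysis_onset(l, 1.0) == pytest.approx(4.0)
        assert lysis_onset(LysisParams(t0=1.0, tau=2.0), 0.001) == pytest.approx(7.0)

    def test_onset_clamped_at_zero(self):
        assert lysis_onset(LysisParams(t0=1.0, tau=1.0), 100.0) == 0.0

    def test_null_phage_equals_control(self):
        g = GrowthParams()
        l = LysisParams(lam=0.0, floor=0.0, regrow_frac=0.0)
        c = simulate_infected_curve(g, l, moi=0.1, seed=0)
        np.testing.assert_allclose(c.od, logistic_od(g.grid, g), atol=1e-12)

    def test_regrowth_lifts_late_od(self):
        g = GrowthParams()
        l = LysisParams(t0=2.0, tau=0.0, lam=3.0, floor=0.02)
        base = infected_od(g.grid, g, l, 0.1)
        regrown = infected_od(g.grid, g, l, 0.1, regrow_at=8.0)
        late = g.grid > 12
        assert np.all(regrown[late] >= base[late])
        assert regrown[-1] > base[-1] + 0.05


class TestHostRangeGenerator:
    def test_block_diagonal_at_extreme_probs(self):
        m = simulate_host_range(3, 9, genus_blocks=[[0], [1], [2]],
                                p_within=1.0, p_between=0.0, p_reduced=0.0,
                                seed=5)
        for p in m.phages:
            col = [m.calls.at[s, p] for s in m.strains]
            assert set(col) <= {LYSIS, NO_LYSIS}

    def test_seed_determinism(self):
        a = simulate_host_range(5, 20, seed=9)
        b = simulate_host_range(5, 20, seed=9)
        assert a.calls.equals(b.calls)

    def test_generated_matrix_passes_validators(self, tmp_path):
        from phagepst.io_tables import read_host_range, write_host_range
        m = simulate_host_range(6, 25, seed=2)
        p = tmp_path / "hr.tsv"
        write_host_range(m, p)
        back = read_host_range(p, "DPA")
        assert back.calls.equals(m.calls)

    def test_planted_set_is_unique_optimum(self):
        planted = [1, 3, 4]
        m = simulate_host_range(7, 18, planted_set=planted, seed=13)
        res = optimize_cocktail(m, 3, method="exhaustive")
        expected = tuple(sorted(m.phages[i] for i in planted))
        assert res.optimal_sets == (expected,)

    def test_infeasible_planting_rejected(self):
        with pytest.raises(errors.GenerationError):
            simulate_host_range(4, 2, planted_set=[0, 1, 2], seed=0)


class TestAntibiogramGenerator:
    def test_extreme_probabilities(self):
        bps = example_breakpoints()
        classes = ("penicillins", "cephalosporins", "carbapenems",
                   "fluoroquinolones")
        all_r = simulate_antibiogram(10, bps, {c: 1.0 for c in classes}, seed=0)
        assert all(classify_mrgn(ab, bps).value == "4MRGN" for ab in all_r)
        all_s = simulate_antibiogram(10, bps, {c: 0.0 for c in classes}, seed=0)
        assert all(classify_mrgn(ab, bps).value == "none" for ab in all_s)

    def test_three_class_fraction_matches_binomial(self):
        """P(exactly 3 of 4 classes R) at p=0.782 is ~0.417; check within 3 sd."""
        p = 0.782
        bps = example_breakpoints()
        classes = ("penicillins", "cephalosporins", "carbapenems",
                   "fluoroquinolones")
        n = 1000
        abs_ = simulate_antibiogram(n, bps, {c: p for c in classes}, seed=7)
        frac3 = np.mean([classify_mrgn(ab, bps).value == "3MRGN" for ab in abs_])
        expected = 4 * p ** 3 * (1 - p)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac3 - expected) < 3 * sd


class TestEndToEndRecovery:
    def test_full_kill_vp_matches_closed_form(self):
        """Noise-free total-kill ladder: pipeline vp equals the analytic value."""
        g = GrowthParams(noise_sd=0.0)
        kill = LysisParams(t0=0.0, tau=0.0, lam=1e9, floor=0.0)
        series = simulate_moi_series(g, kill, "phi", "s", seed=1)
        res = global_virulence(series)
        # oracle: control is strictly increasing so onset falls back to 24 h;
        # the infected AUC is the single first trapezoid 0.1 * 0.25 / 2
        ctrl = logistic_od(g.grid, g)
        assert np.all(np.diff(ctrl) > 0)
        vp_closed = 1 - (0.1 * 0.25 / 2) / np.trapezoid(ctrl, g.grid)
        assert res.vp == pytest.approx(vp_closed, abs=1e-6)
        assert res.vp >= 0.75

    def test_noisy_full_kill_vp_near_closed_form(self):
        g0 = GrowthParams(noise_sd=0.0)
        kill = LysisParams(t0=0.0, tau=0.0, lam=1e9, floor=0.0)
        ctrl = logistic_od(g0.grid, g0)
        vp_closed = 1 - (0.1 * 0.25 / 2) / np.trapezoid(ctrl, g0.grid)
        g = GrowthParams(noise_sd=0.02)
        vps = [global_virulence(simulate_moi_series(g, kill, "phi", "s",
                                                    seed=s)).vp
               for s in range(20)]
        assert abs(np.mean(vps) - vp_closed) < 0.05

    def test_null_phage_gives_no_lysis_and_tiny_vp(self):
        g = GrowthParams(noise_sd=0.02)
        null = LysisParams(lam=0.0, floor=0.0, regrow_frac=0.0)
        vps = []
        for s in range(5):
            series = simulate_moi_series(g, null, "phi", "s", seed=s)
            res = global_virulence(series)
            vps.append(res.vp)
        assert max(vps) < 0.05

    def test_planted_cocktail_recovered_from_simulated_plate(self, tmp_path):
        """simulate -> write tables -> read -> PKA calls -> optimizer finds S*."""
        from phagepst.io_tables import read_plate, write_plate
        truth = simulate_host_range(6, 16, planted_set=[0, 2, 5], seed=21,
                                    assay="PKA", p_reduced=0.0)
        g = GrowthParams(noise_sd=0.01)
        plate = simulate_pka_plate(truth, g, LysisParams(), seed=21)
        sp, mp = tmp_path / "series.tsv", tmp_path / "map.tsv"
        write_plate(plate, sp, mp)
        results = pka_table(read_plate(sp, mp))
        matrix = pka_matrix(results)
        assert matrix.calls.equals(truth.calls.loc[matrix.strains, matrix.phages])
        res = optimize_cocktail(matrix, 3, method="exhaustive")
        expected = tuple(sorted(truth.phages[i] for i in [0, 2, 5]))
        assert res.optimal_sets == (expected,)
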