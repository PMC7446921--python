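"""Indicator values, change points, permutation tests and TITAN filters
against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from shalehealth import titan


def indval_oracle(occ, upper_mask):
    """Direct A*B computation of the group indicator values."""
    m_lo, m_up = occ[~upper_mask].mean(), occ[upper_mask].mean()
    a_lo = m_lo / (m_lo + m_up)
    a_up = m_up / (m_lo + m_up)
    b_lo, b_up = occ[~upper_mask].mean(), occ[upper_mask].mean()  # binary: fidelity = rate
    return 100 * a_lo * b_lo, 100 * a_up * b_up


def best_changepoint_oracle(occ, grad, min_split):
    """Exhaustive enumeration of all admissible splits."""
    order = np.argsort(grad, kind="stable")
    g, o = grad[order], occ[order]
    n = len(g)
    best = None
    for i in range(min_split, n - min_split + 1):
        if g[i - 1] >= g[i]:
            continue
        upper = np.zeros(n, dtype=bool)
        upper[i:] = True
        iv_lo, iv_up = indval_oracle(o, upper)
        score = max(iv_lo, iv_up)
        cp = 0.5 * (g[i - 1] + g[i])
        if best is None or score > best[1] + 1e-12:
            best = (cp, score, "positive" if iv_up >= iv_lo else "inverse")
    return best


class TestIndval:
    def test_perfect_indicator(self):
        occ = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        upper = np.arange(10) >= 5
        (iv_lo, iv_up), best = titan.indval(occ, upper)
        assert iv_up == pytest.approx(100.0)
        assert iv_lo == 0.0
        assert best == 1

    def test_uniform_presence_gives_50_50(self):
        occ = np.ones(12)
        upper = np.arange(12) >= 6
        (iv_lo, iv_up), _ = titan.indval(occ, upper)
        assert iv_lo == pytest.approx(50.0) and iv_up == pytest.approx(50.0)

    def test_matches_direct_formula_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            occ = rng.integers(0, 2, 12).astype(float)
            if occ.sum() == 0:
                continue
            k = rng.integers(1, 12)
            upper = np.arange(12) >= k
            (iv_lo, iv_up), best = titan.indval(occ, upper)
            e_lo, e_up = indval_oracle(occ, upper)
            assert iv_lo == pytest.approx(e_lo, rel=1e-12)
            assert iv_up == pytest.approx(e_up, rel=1e-12)
            assert best == (1 if e_up >= e_lo else 0)

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            titan.indval(np.zeros(10), np.arange(10) >= 5)
        with pytest.raises(ValueError):
            titan.indval(np.ones(10), np.zeros(10, dtype=bool))


class TestBestChangepoint:
    def test_perfect_step_top4(self):
        grad = np.arange(10, dtype=float)
        occ = (grad >= 6).astype(float)  # present exactly in the top 4
        cp, iv, direction = titan.best_changepoint(occ, grad, min_split=3)
        assert cp == pytest.approx(5.5)  # midpoint of the 6th and 7th sorted values
        assert iv == pytest.approx(100.0)
        assert direction == "positive"

    def test_mirrored_step_is_inverse(self):
        grad = np.arange(10, dtype=float)
        occ = (grad <= 3).astype(float)
        cp, iv, direction = titan.best_changepoint(occ, grad, min_split=3)
        assert cp == pytest.approx(3.5)
        assert iv == pytest.approx(100.0)
        assert direction == "inverse"

    def test_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = 30
            grad = rng.normal(size=n)
            occ = rng.integers(0, 2, n).astype(float)
            if occ.sum() == 0:
                continue
            got = titan.best_changepoint(occ, grad, min_split=5)
            exp = best_changepoint_oracle(occ, grad, min_split=5)
            assert got[0] == pytest.approx(exp[0], rel=1e-12)
            assert got[1] == pytest.approx(exp[1], rel=1e-12)
            assert got[2] == exp[2]

    def test_all_patterns_over_fixed_gradient(self):
        # oracle equivalence on every non-zero occurrence pattern of 10 samples
        grad = np.linspace(0.0, 9.0, 10)
        for bits in itertools.product((0.0, 1.0), repeat=10):
            occ = np.array(bits)
            if occ.sum() == 0:
                continue
            got = titan.best_changepoint(occ, grad, min_split=3)
            exp = best_changepoint_oracle(occ, grad, min_split=3)
            assert got[0] == pytest.approx(exp[0]) and got[1] == pytest.approx(exp[1])
            assert got[2] == exp[2]

    def test_monotone_gradient_transform_invariance(self):
        rng = np.random.default_rng(2)
        grad = rng.uniform(0, 10, 40)
        occ = (grad + rng.normal(0, 2, 40) > 6).astype(float)
        cp1, iv1, d1 = titan.best_changepoint(occ, grad, min_split=5)
        cp2, iv2, d2 = titan.best_changepoint(occ, np.exp(grad / 5), min_split=5)
        assert iv1 == pytest.approx(iv2) and d1 == d2
        # only the change point's coordinates move under the transform
        assert cp2 != cp1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            titan.best_changepoint(np.ones(8), np.arange(8.0), min_split=5)

    def test_constant_gradient_rejected(self):
        with pytest.raises(ValueError):
            titan.best_changepoint(np.ones(20), np.zeros(20), min_split=5)


class TestPermutationZ:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        grad = rng.normal(size=40)
        occ = rng.integers(0, 2, 40).astype(float)
        r1 = titan.permutation_z(occ, grad, seed=11)
        r2 = titan.permutation_z(occ, grad, seed=11)
        assert r1 == r2

    def test_perfect_step_is_extreme(self):
        grad = np.arange(40, dtype=float)
        occ = (grad >= 25).astype(float)
        z, p = titan.permutation_z(occ, grad, n_perm=250, seed=0)
        assert p <= 0.01
        assert z > 2

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            titan.permutation_z(np.ones(20), np.arange(20.0), n_perm=50)

    def test_pvalue_never_zero(self):
        grad = np.arange(30, dtype=float)
        occ = (grad >= 20).astype(float)
        _, p = titan.permutation_z(occ, grad, n_perm=250, seed=1)
        assert p >= 1.0 / 251.0


class TestBootstrapDiagnostics:
    def test_perfect_step_high_purity(self):
        grad = np.arange(40, dtype=float)
        occ = (grad >= 25).astype(float)
        purity, reliability = titan.bootstrap_diagnostics(occ, grad, n_boot=200, n_perm=100, seed=2)
        assert purity >= 0.95
        assert reliability >= 0.9

    def test_noise_low_reliability(self):
        rng = np.random.default_rng(4)
        grad = rng.normal(size=60)
        occ = rng.integers(0, 2, 60).astype(float)
        purity, reliability = titan.bootstrap_diagnostics(occ, grad, n_boot=200, n_perm=100, seed=3)
        assert 0.0 <= purity <= 1.0
        assert reliability < 0.5

    def test_bounds_always(self):
        rng = np.random.default_rng(5)
        for s in range(3):
            grad = rng.uniform(0, 1, 30)
            occ = (rng.random(30) < 0.4).astype(float)
            if occ.sum() == 0:
                continue
            purity, reliability = titan.bootstrap_diagnostics(
                occ, grad, n_boot=100, n_perm=100, seed=s
            )
            assert 0.0 <= purity <= 1.0 and 0.0 <= reliability <= 1.0


class TestRunTitan:
    def make_matrix(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        grad = rng.gamma(2.0, 1.0, n)
        sym = pd.DataFrame(
            {
                "rare": (np.arange(n) < 4).astype(int),  # frequency 4: below the entry filter
                "step": (grad > np.quantile(grad, 0.6)).astype(int),
                "noise": rng.integers(0, 2, n),
            }
        )
        return sym, grad

    def test_low_frequency_symptoms_excluded(self):
        sym, grad = self.make_matrix()
        table = titan.run_titan(sym, grad, n_perm=100, n_boot=0, seed=0)
        assert "rare" not in set(table["symptom"])
        assert {"step", "noise"} <= set(table["symptom"])

    def test_same_seed_identical_tables(self):
        sym, grad = self.make_matrix(seed=1)
        t1 = titan.run_titan(sym, grad, n_perm=100, n_boot=100, seed=42)
        t2 = titan.run_titan(sym, grad, n_perm=100, n_boot=100, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_constant_gradient_rejected(self):
        sym, _ = self.make_matrix()
        with pytest.raises(ValueError):
            titan.run_titan(sym, np.ones(len(sym)), n_boot=0)

    def test_signal_recovery_on_synthetic_cohorts(self):
        # 60 symptoms, 10 gradient-responsive, null dose-response on totals:
        # most responsive symptoms flagged, few null ones (median over 20 seeds)
        import shalehealth.simulate as sim

        hit_counts, false_rates = [], []
        for s in range(20):
            cfg = sim.SimulationConfig(
                seed=2000 + s,
                n_respondents=104,
                n_wells=400,
                n_symptoms=60,
                n_responsive_symptoms=10,
                dose_response_beta=0.0,
            )
            wells = sim.generate_wells(cfg)
            resp = sim.generate_respondents(cfg, wells)
            sym = resp[[c for c in resp if c.startswith("sym_")]].rename(columns=lambda c: c[4:])
            table = titan.run_titan(
                sym, resp["true_exposure"].to_numpy(), n_boot=0, n_perm=250, seed=s
            )
            responsive = set(resp.attrs["responsive_symptoms"])
            sig = set(table.loc[table["significant"], "symptom"])
            analysed = set(table["symptom"])
            hit_counts.append(len(sig & responsive & analysed))
            null_analysed = analysed - responsive
            false_rates.append(len(sig - responsive) / max(len(null_analysed), 1))
        assert np.median(hit_counts) >= 8
        assert np.median(false_rates) <= 0.05


class TestReportFilter:
    def make_results(self):
        return pd.DataFrame(
            {
                "symptom": ["a", "b", "c", "d"],
                "frequency": [10, 11, 30, 25],
                "change_point": [1.0, 1.0, 2.0, 2.0],
                "indicator_value": [60.0, 50.0, 70.0, 80.0],
                "direction": ["positive", "positive", "inverse", "positive"],
                "z_score": [2.0, 1.0, 0.9, 3.0],
                "p_value": [0.01, 0.04, 0.01, 0.2],
                "purity": [1.0] * 4,
                "reliability": [1.0] * 4,
                "significant": [True, True, True, False],
            }
        )

    def test_boundary_conventions(self):
        out = titan.report_filter(self.make_results())
        # a: frequency exactly 10 -> excluded (strict >10); b: z exactly 1.0 -> kept;
        # c: z < 1 -> excluded; d: p > alpha -> excluded
        assert list(out["symptom"]) == ["b"]

    def test_sorted_by_indicator_value(self):
        res = self.make_results()
        res["frequency"] = 20
        res["z_score"] = [2.0, 1.5, 1.2, 3.0]
        res["p_value"] = 0.01
        out = titan.report_filter(res)
        assert (np.diff(out["indicator_value"]) <= 0).all()

    def test_empty_survivors_valid_schema(self):
        res = self.make_results()
        res["p_value"] = 0.9
        out = titan.report_filter(res)
        assert len(out) == 0 and list(out.columns) == list(res.columns)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            titan.report_filter(self.make_results().iloc[:0])
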