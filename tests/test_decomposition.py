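"""Scale-factor estimation: peak-IV ratios, the linear decomposition with
its NNLS oracle, seed-repeat convergence and contribution scores."""

import numpy as np
import pytest

from ipsctailor.clamp import peak_iv
from ipsctailor.decomposition import (
    DASH_THRESHOLD,
    DEFAULT_COMPONENTS,
    build_component_matrix,
    contribution_scores,
    estimate_peak_scale,
    fit_decomposition,
    repeat_fit_convergence,
)
from ipsctailor.synthetic import SyntheticCellSpec, synth_outward_trace


class TestPeakScale:
    def test_identity(self):
        iv = np.array([-1.0, -5.0, -3.0])
        assert estimate_peak_scale(iv, iv) == 1.0

    def test_proportional(self):
        iv = np.array([-1.0, -5.0, -3.0])
        assert estimate_peak_scale(0.5 * iv, iv) == pytest.approx(0.5)

    def test_zero_peak_rejected(self):
        with pytest.raises(ZeroDivisionError):
            estimate_peak_scale(np.zeros(3), np.zeros(3))

    @pytest.mark.parametrize("factor", [0.69, 0.80])
    def test_recovers_cell_line_inward_scalings(self, sodium_clamp, factor):
        """A measured IV built as factor x simulated recovers the factor
        (0.69 and 0.80 are the fitted I_Na / I_CaL line scalings)."""
        comps, _ = sodium_clamp
        simulated = peak_iv(comps["I_Na"], "inward", respect_mask=False)
        measured = factor * simulated
        assert estimate_peak_scale(measured, simulated) == pytest.approx(factor)


class TestComponentMatrix:
    def test_default_has_eight_components_in_order(self, component_matrix):
        assert component_matrix.component_names == DEFAULT_COMPONENTS
        assert component_matrix.matrix.shape[0] == 8

    def test_subset_two_components(self, component_matrix):
        sub = component_matrix.subset(("I_Ks", "I_NaCa"))
        assert sub.matrix.shape[0] == 2
        assert sub.component_names == ("I_Ks", "I_NaCa")

    def test_rows_match_clamp_component_traces(self, component_matrix,
                                               outward_clamp):
        comps, _ = outward_clamp
        for name in ("I_Ks", "I_NaCa"):
            k = component_matrix.component_names.index(name)
            row = component_matrix.matrix_full[k]
            expected = comps[name].data.T.ravel()
            np.testing.assert_allclose(row, expected, rtol=1e-12)

    def test_columns_exclude_masked_samples(self, component_matrix):
        times = component_matrix.column_map[~component_matrix.mask, 1]
        assert np.all(times >= component_matrix.protocol.mask_after_change)


class TestFit:
    def test_noise_free_recovery_is_exact(self, component_matrix):
        spec = SyntheticCellSpec(true_s={"I_Ks": 52.0, "I_NaCa": 1.7},
                                 seed=3, noise_sd=0.0)
        trace = synth_outward_trace(spec, component_matrix,
                                    add_transient=False)
        fit = fit_decomposition(component_matrix, trace, method="nnls")
        truth = np.array([spec.true_s.get(n, 0.0) for n in DEFAULT_COMPONENTS])
        err = np.linalg.norm(fit.s_vector(DEFAULT_COMPONENTS) - truth)
        assert err < 1e-5

    def test_cmaes_agrees_with_nnls_oracle(self, component_matrix,
                                           synthetic_trace):
        _, trace = synthetic_trace
        r1 = fit_decomposition(component_matrix, trace, method="cmaes", seed=5)
        r2 = fit_decomposition(component_matrix, trace, method="nnls")
        a = r1.s_vector(DEFAULT_COMPONENTS)
        b = r2.s_vector(DEFAULT_COMPONENTS)
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-3

    def test_absent_components_below_dash_threshold(self, component_matrix):
        spec = SyntheticCellSpec(true_s={"I_Ks": 139.0, "I_NaCa": 3.32},
                                 seed=7, noise_sd=0.0)
        trace = synth_outward_trace(spec, component_matrix,
                                    add_transient=False)
        fit = fit_decomposition(component_matrix, trace, method="cmaes", seed=2)
        absent = {n for n in DEFAULT_COMPONENTS if n not in spec.true_s}
        assert fit.absent() == absent
        for name in absent:
            assert fit.s[name] < DASH_THRESHOLD

    def test_grid_mismatch_rejected(self, component_matrix):
        with pytest.raises(ValueError):
            fit_decomposition(component_matrix, np.zeros(17), method="nnls")


class TestSeedRepeat:
    def test_two_seeds_return_one_entry(self, component_matrix,
                                        synthetic_trace):
        _, trace = synthetic_trace
        l2 = repeat_fit_convergence(component_matrix, trace, n_seeds=2)
        assert len(l2) == 1

    def test_deterministic_method_gives_exact_zero(self, component_matrix,
                                                   synthetic_trace):
        _, trace = synthetic_trace
        l2 = repeat_fit_convergence(component_matrix, trace, n_seeds=3,
                                    method="nnls")
        assert l2 == [0.0, 0.0]

    def test_too_few_seeds_rejected(self, component_matrix, synthetic_trace):
        _, trace = synthetic_trace
        with pytest.raises(ValueError):
            repeat_fit_convergence(component_matrix, trace, n_seeds=1)


class TestContributionScores:
    def test_equal_final_currents_split_evenly(self):
        c = contribution_scores({"a": 1.0, "b": 1.0}, {"a": 2.0, "b": -2.0})
        assert c == {"a": 0.5, "b": 0.5}

    def test_scores_sum_to_one(self, component_matrix, synthetic_trace):
        _, trace = synthetic_trace
        fit = fit_decomposition(component_matrix, trace, method="nnls")
        assert sum(fit.c.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_common_rescaling(self):
        s = {"a": 3.0, "b": 0.5}
        finals = {"a": 1.2, "b": -0.4}
        c1 = contribution_scores(s, finals)
        c2 = contribution_scores({k: 17.0 * v for k, v in s.items()}, finals)
        for k in s:
            assert c1[k] == pytest.approx(c2[k], rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            contribution_scores({"a": 0.0}, {"a": 0.0})
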