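"""Control detection, panel editing, and robust-model normalization."""

import numpy as np
import pandas as pd
import pytest

from proma import (
    ControlPanel,
    apply_normalization,
    build_control_observations,
    detect_controls,
    edit_panel,
    fit_rlm,
)
from proma.controls import ControlObservations, match_control_types
from proma.errors import ContractError, DesignMatrixError, PanelError
from proma.preprocess import ExperimentMatrix

from test_preprocess import _matrix


def _obs(y, array, block, ctype):
    table = pd.DataFrame({"y": y, "array": array, "block": block,
                          "type": ctype})
    return ControlObservations(
        table=table,
        array_levels=sorted(set(array)),
        block_levels=sorted(set(block)),
        type_levels=list(dict.fromkeys(ctype)),
    )


def _grid_obs(alpha, beta, gamma, mu=10.0, noise=None, rng=None):
    """Full type × array × block grid with known effects (reference = 0)."""
    y, arrays, blocks, types = [], [], [], []
    tlabels = list(gamma)
    for t in tlabels:
        for a in range(1, len(alpha) + 1):
            for b in range(1, len(beta) + 1):
                y.append(mu + gamma[t] + alpha[a - 1] + beta[b - 1])
                arrays.append(a)
                blocks.append(b)
                types.append(t)
    y = np.asarray(y)
    if noise is not None:
        y = y + noise
    return _obs(y, arrays, blocks, types)


class TestDetect:
    def test_default_patterns_flag_igg(self):
        m = _matrix([[1.0], [2.0]], stage="averaged",
                    ids=["Anti-Human IgG 0.5ug", "ordinary protein"])
        panel = detect_controls(m)
        assert panel.entries == [("Anti-Human IgG 0.5ug", "IgG")]
        assert panel.source == "auto"

    def test_empty_pattern_list_gives_empty_panel(self, small_logged):
        assert detect_controls(small_logged, patterns=[]).entries == []

    def test_synthetic_controls_found_exactly(self, small_run, small_logged):
        _, truth = small_run
        panel = detect_controls(small_logged)
        assert sorted(panel.ids) == sorted(truth.control_ids)
        for pid, t in panel.entries:
            assert t == truth.control_type_of[pid]

    def test_first_matching_pattern_wins(self):
        m = _matrix([[1.0]], stage="averaged", ids=["biotin control spot"])
        panel = detect_controls(
            m, patterns=[(r"biotin", "Biotin"), (r"control", "Control")]
        )
        assert panel.entries == [("biotin control spot", "Biotin")]


class TestEditPanel:
    def _panel(self):
        return ControlPanel([("A", "IgG"), ("B", "Biotin")], source="auto")

    def test_removal_wins_over_addition(self):
        out = edit_panel(self._panel(), add=[("C", "IgG")], remove=["C"])
        assert "C" not in out.ids

    def test_empty_edits_identity_with_merged_source(self):
        out = edit_panel(self._panel())
        assert out.entries == self._panel().entries
        assert out.source == "merged"

    def test_removing_nonmember_is_noop(self):
        out = edit_panel(self._panel(), remove=["ZZZ"])
        assert out.ids == ["A", "B"]

    def test_unknown_addition_rejected(self):
        with pytest.raises(PanelError, match="XYZ"):
            edit_panel(self._panel(), add=[("XYZ", "IgG")],
                       known_ids=["A", "B"])

    def test_duplicate_ids_rejected_by_panel(self):
        with pytest.raises(ContractError, match="duplicate"):
            ControlPanel([("A", "IgG"), ("A", "Biotin")])


class TestBuildObservations:
    def test_cartesian_count(self, small_run, small_logged, small_panel):
        _, truth = small_run
        obs = build_control_observations(small_logged, small_panel)
        n_controls = len(truth.control_ids)
        n_samples = len(truth.sample_names)
        assert len(obs.table) == n_controls * truth.config.n_blocks * n_samples
        assert obs.array_levels == list(range(1, n_samples + 1))

    def test_single_sample_degenerate_index(self, small_run):
        files, _ = small_run
        from conftest import pipeline_to_logged

        logged = pipeline_to_logged(files[:1])
        panel = detect_controls(logged)
        obs = build_control_observations(logged, panel)
        assert set(obs.table["array"]) == {1}

    def test_absent_protein_rejected(self, small_logged):
        panel = ControlPanel([("NOT_THERE", "IgG"), ("ALSO_NOT", "IgG")])
        with pytest.raises(PanelError, match="NOT_THERE"):
            build_control_observations(small_logged, panel)

    def test_mixed_block_control_rejected(self):
        m = _matrix([[1.0]], stage="logged", ids=["C"], blocks=[-1])
        m.annotations.at[0, "source_blocks"] = (1, 2)
        with pytest.raises(ContractError, match="across blocks"):
            build_control_observations(m, ControlPanel([("C", "IgG")]))


class TestFitRLM:
    def test_exact_recovery_noise_free(self):
        obs = _grid_obs(alpha=[0.0, 1.0], beta=[0.0], gamma={"IgG": 0.0})
        fit = fit_rlm(obs)
        assert fit.array_effects[1] == 0.0
        assert abs(fit.array_effects[2] - 1.0) < 1e-8
        assert fit.converged

    def test_degenerate_single_array_block_two_types(self):
        obs = _obs([4.0, 4.0, 8.0, 8.0], [1, 1, 1, 1], [1, 1, 1, 1],
                   ["a", "a", "b", "b"])
        fit = fit_rlm(obs)
        assert fit.array_effects == {1: 0.0}
        assert fit.block_effects == {1: 0.0}
        # fitted per-type means: intercept + gamma
        assert abs(fit.intercept + fit.type_effects["a"] - 4.0) < 1e-8
        assert abs(fit.intercept + fit.type_effects["b"] - 8.0) < 1e-8

    def test_outlier_resistance_beats_ols(self, rng):
        alpha = [0.0, 0.8, -0.5, 0.3, 1.2, -0.9]
        beta = [0.0, 0.4, -0.3, 0.2, -0.6, 0.5, 0.1, -0.2]
        gamma = {"IgG": 0.0, "Biotin": -1.0, "Alexa": 0.5}
        n = len(alpha) * len(beta) * len(gamma)
        noise = rng.normal(0, 0.05, n)
        hits = rng.random(n) < 0.10
        noise = noise + hits * 5.0  # gross one-sided outliers
        obs = _grid_obs(alpha, beta, gamma, noise=noise)

        fit = fit_rlm(obs)
        err_huber = max(
            max(abs(fit.array_effects[a + 1] - alpha[a])
                for a in range(len(alpha))),
            max(abs(fit.block_effects[b + 1] - beta[b])
                for b in range(len(beta))),
        )
        assert err_huber < 0.05

        # normal-equations OLS oracle on the same design
        from proma.controls import _design_matrix

        X, names = _design_matrix(obs)
        y = obs.table["y"].to_numpy()
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        coef = dict(zip(names, beta_ols))
        err_ols = max(
            max(abs(coef[f"array[{a + 1}]"] - alpha[a])
                for a in range(1, len(alpha))),
            max(abs(coef[f"block[{b + 1}]"] - beta[b])
                for b in range(1, len(beta))),
        )
        assert err_ols > err_huber

    def test_huge_huber_c_matches_ols_oracle(self, rng):
        alpha = [0.0, 0.5, -0.2]
        beta = [0.0, 0.3]
        gamma = {"IgG": 0.0, "Biotin": 1.0}
        n = len(alpha) * len(beta) * len(gamma)
        obs = _grid_obs(alpha, beta, gamma, noise=rng.normal(0, 0.3, n))
        fit = fit_rlm(obs, huber_c=1e6)

        from proma.controls import _design_matrix

        X, names = _design_matrix(obs)
        y = obs.table["y"].to_numpy()
        coef = dict(zip(names, np.linalg.solve(X.T @ X, X.T @ y)))
        for term, value in coef.items():
            if term == "intercept":
                assert abs(fit.intercept - value) < 1e-6
            elif term.startswith("array"):
                a = int(term[6:-1])
                assert abs(fit.array_effects[a] - value) < 1e-6
            elif term.startswith("block"):
                b = int(term[6:-1])
                assert abs(fit.block_effects[b] - value) < 1e-6

    def test_matches_statsmodels_rlm(self, rng):
        # independent implementation of the same Huber/MAD IRLS recipe
        import statsmodels.api as sm

        alpha = [0.0, 0.7, -0.4]
        beta = [0.0, 0.25, -0.15, 0.4]
        gamma = {"IgG": 0.0, "Biotin": -0.8}
        n = len(alpha) * len(beta) * len(gamma)
        noise = rng.normal(0, 0.2, n)
        noise[::11] += 3.0
        obs = _grid_obs(alpha, beta, gamma, noise=noise)
        fit = fit_rlm(obs, tol=1e-10, max_iter=200)

        from proma.controls import _design_matrix

        X, _ = _design_matrix(obs)
        y = obs.table["y"].to_numpy()
        sm_fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad"
        )
        ours = np.r_[
            fit.intercept,
            [fit.type_effects[t] for t in obs.type_levels[1:]],
            [fit.array_effects[a] for a in obs.array_levels[1:]],
            [fit.block_effects[b] for b in obs.block_levels[1:]],
        ]
        np.testing.assert_allclose(ours, sm_fit.params, atol=5e-4)

    def test_shift_equivariance(self, rng):
        alpha = [0.0, 0.5]
        beta = [0.0, -0.3]
        gamma = {"IgG": 0.0, "Biotin": 0.7}
        n = len(alpha) * len(beta) * len(gamma)
        noise = rng.normal(0, 0.2, n)
        obs = _grid_obs(alpha, beta, gamma, noise=noise)
        fit0 = fit_rlm(obs)
        shifted = _obs(
            obs.table["y"].to_numpy() + 3.5,
            obs.table["array"].tolist(),
            obs.table["block"].tolist(),
            obs.table["type"].tolist(),
        )
        fit1 = fit_rlm(shifted)
        assert abs(fit1.intercept - fit0.intercept - 3.5) < 1e-6
        for a in fit0.array_effects:
            assert abs(fit1.array_effects[a] - fit0.array_effects[a]) < 1e-6
        for b in fit0.block_effects:
            assert abs(fit1.block_effects[b] - fit0.block_effects[b]) < 1e-6

    def test_fully_degenerate_rejected(self):
        obs = _obs([1.0, 2.0], [1, 1], [1, 1], ["IgG", "IgG"])
        with pytest.raises(DesignMatrixError, match="degenerate"):
            fit_rlm(obs)

    def test_rank_deficiency_names_columns(self):
        # block 2 occurs only in array 2 and vice versa: confounded
        obs = _obs([1.0, 2.0, 1.1, 2.1], [1, 2, 1, 2], [1, 2, 1, 2],
                   ["IgG", "IgG", "IgG", "IgG"])
        with pytest.raises(DesignMatrixError, match=r"array\[2\]|block\[2\]"):
            fit_rlm(obs)

    def test_deterministic(self, rng):
        obs = _grid_obs([0.0, 0.5], [0.0, -0.3], {"IgG": 0.0},
                        noise=rng.normal(0, 0.1, 4))
        f1, f2 = fit_rlm(obs), fit_rlm(obs)
        assert f1 == f2


class TestApplyNormalization:
    def test_zero_coefficients_identity(self, small_logged):
        from proma.controls import RLMFit

        fit = RLMFit(
            intercept=5.0,
            type_effects={"IgG": 0.0},
            array_effects={a: 0.0 for a in small_logged.sample_to_array_index},
            block_effects={b: 0.0 for b in range(1, 5)},
            huber_c=1.345, scale=0.1, n_iterations=1, converged=True,
        )
        out = apply_normalization(small_logged, fit)
        np.testing.assert_array_equal(out.values, small_logged.values)
        assert out.stage == "normalized"

    def test_recovers_bias_free_truth(self, small_run, small_logged,
                                      small_panel):
        files, truth = small_run
        obs = build_control_observations(small_logged, small_panel)
        fit = fit_rlm(obs)
        normalized = apply_normalization(small_logged, fit)

        # Treatment coding leaves the reference-level biases in place, so
        # normalized values sit at true mean + alpha*_1 + beta*_1.
        shift = truth.array_offsets[0] + truth.block_offsets[0]
        ids = normalized.row_keys().to_numpy()
        groups = np.array(truth.sample_groups)
        devs = []
        for i, pid in enumerate(ids):
            if pid not in truth.true_means.index:
                continue
            for g in set(groups):
                expect = truth.true_means.loc[pid, g] + shift
                got = normalized.values[i, groups == g]
                devs.extend(np.abs(got - expect))
        assert np.median(devs) < truth.config.noise_sd

    def test_between_array_control_variance_shrinks(
        self, small_logged, small_panel
    ):
        obs = build_control_observations(small_logged, small_panel)
        fit = fit_rlm(obs)
        normalized = apply_normalization(small_logged, fit)
        control_rows = small_logged.row_keys().isin(small_panel.ids).to_numpy()
        var_before = np.nanvar(small_logged.values[control_rows], axis=1).mean()
        var_after = np.nanvar(normalized.values[control_rows], axis=1).mean()
        assert var_after <= var_before

    def test_refit_on_normalized_controls_is_null(self):
        obs = _grid_obs(alpha=[0.0, 1.0, -0.5], beta=[0.0, 0.4],
                        gamma={"IgG": 0.0, "Biotin": 1.0})
        fit = fit_rlm(obs)
        # normalize the observations themselves and refit
        t = obs.table
        y2 = t["y"].to_numpy() - np.array(
            [fit.array_effects[a] for a in t["array"]]
        ) - np.array([fit.block_effects[b] for b in t["block"]])
        refit = fit_rlm(_obs(y2, t["array"].tolist(), t["block"].tolist(),
                             t["type"].tolist()))
        for a, v in refit.array_effects.items():
            assert abs(v) < 1e-7
        for b, v in refit.block_effects.items():
            assert abs(v) < 1e-7

    def test_rows_and_annotations_preserved(self, small_logged, small_panel):
        obs = build_control_observations(small_logged, small_panel)
        fit = fit_rlm(obs)
        out = apply_normalization(small_logged, fit)
        pd.testing.assert_frame_equal(out.annotations,
                                      small_logged.annotations)
        assert out.sample_names == small_logged.sample_names

    def test_mixed_block_rows_get_mean_beta(self):
        m = _matrix([[10.0]], stage="logged", ids=["P"], blocks=[-1])
        m.annotations.at[0, "source_blocks"] = (1, 2)
        from proma.controls import RLMFit

        fit = RLMFit(
            intercept=0.0, type_effects={},
            array_effects={1: 0.0},
            block_effects={1: 0.0, 2: 0.4},
            huber_c=1.345, scale=0.1, n_iterations=1, converged=True,
        )
        out = apply_normalization(m, fit)
        assert abs(out.values[0, 0] - (10.0 - 0.2)) < 1e-12
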