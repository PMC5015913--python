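"""Anchored paired-comparison probit: design, MLE, anchoring, holdout."""



import numpy as np
import pytest
from scipy.stats import norm

import dweights as dw
from dweights.pc_model import (
    AnchoringError,
    SeparationError,
    anchor_to_dw,
    build_design,
    estimates_to_frame,
    fit_probit,
    predicted_probabilities,
    split_and_validate,
)
from dweights.survey_sim import (
    ANCHOR_DEAD,
    ANCHOR_FULL_HEALTH,
    HealthState,
    PCResponse,
    StateRegistry,
    TrueWeights,
)


def tiny_registry(n_sub=2):
    states = [HealthState("FH", anchor=ANCHOR_FULL_HEALTH)]
    states += [HealthState(f"S{i}") for i in range(1, n_sub + 1)]
    states += [HealthState("DEAD", anchor=ANCHOR_DEAD)]
    return StateRegistry(states)


from conftest import probit_grid_oracle


class TestDesign:
    def test_reference_column_dropped(self):
        reg = tiny_registry(1)
        pc = [PCResponse("r1", "S1", "DEAD", True)]
        design = build_design(pc, reg)
        assert "DEAD" not in design.columns
        assert design.reference == "DEAD"

    def test_unseen_state_listed_unidentifiable(self):
        reg = tiny_registry(2)
        pc = [PCResponse("r1", "S1", "DEAD", i < 3) for i in range(5)]
        design = build_design(pc, reg)
        assert design.unidentifiable == ["FH", "S2"]
        fit = fit_probit(design)
        assert "S2" not in fit.beta

    def test_label_symmetry(self):
        """Swapping (a, b) and negating the outcome leaves the fit unchanged."""
        reg = tiny_registry(2)
        rng = np.random.default_rng(0)
        pc = []
        for _ in range(200):
            a, b = rng.choice(["FH", "S1", "S2", "DEAD"], 2, replace=False)
            pc.append(PCResponse("r", a, b, bool(rng.random() < 0.5)))
        swapped = [PCResponse(r.respondent_id, r.state_b, r.state_a,
                              not r.chose_a_healthier) for r in pc]
        f1 = fit_probit(build_design(pc, reg))
        f2 = fit_probit(build_design(swapped, reg))
        for s in f1.beta:
            assert f1.beta[s] == pytest.approx(f2.beta[s], abs=1e-6)

    def test_row_and_column_counts(self):
        reg = tiny_registry(1)
        pc = [PCResponse("r", "S1", "DEAD", bool(i % 2)) for i in range(6)]
        pc += [PCResponse("r", "FH", "S1", True) for _ in range(4)]
        design = build_design(pc, reg)
        assert design.n_obs == 10
        assert design.n_params == 2  # FH and S1 identified, DEAD dropped


class TestFit:
    def test_single_pair_closed_form(self):
        """One-parameter probit MLE equals probit of the empirical frequency."""
        reg = tiny_registry(1)
        pc = [PCResponse("r", "S1", "DEAD", i < 84) for i in range(100)]
        fit = fit_probit(build_design(pc, reg))
        assert fit.beta["S1"] == pytest.approx(norm.ppf(0.84), abs=1e-6)
        assert fit.beta["DEAD"] == 0.0

    def test_mle_matches_grid_search_oracle(self):
        reg = tiny_registry(2)
        truth = TrueWeights({"FH": 0.0, "S1": 0.3, "S2": 0.7, "DEAD": 1.0}, reg)
        cfg = dw.SimConfig(n_respondents=20, k_pairs=10, sigma_pc=0.6, seed=21)
        pc = dw.simulate_pc_responses(reg, truth, cfg)
        fit = fit_probit(build_design(pc, reg))
        oracle, oracle_ll = probit_grid_oracle(pc, reg, tol=1e-4)
        for s, b in oracle.items():
            assert abs(b - fit.beta[s]) < 1e-3
        assert fit.loglik >= oracle_ll - 1e-9

    def test_statsmodels_cross_check(self):
        """Independent route: statsmodels Probit on the signed design matrix."""
        import statsmodels.api as sm

        reg = tiny_registry(3)
        truth = TrueWeights(
            {"FH": 0.0, "S1": 0.2, "S2": 0.5, "S3": 0.8, "DEAD": 1.0}, reg)
        cfg = dw.SimConfig(n_respondents=60, k_pairs=10, sigma_pc=0.5, seed=33)
        pc = dw.simulate_pc_responses(reg, truth, cfg)
        design = build_design(pc, reg)
        fit = fit_probit(design)
        X = np.zeros((len(pc), len(design.columns)))
        col = {s: j for j, s in enumerate(design.columns)}
        y = np.zeros(len(pc))
        for i, r in enumerate(pc):
            if r.state_a in col:
                X[i, col[r.state_a]] += 1
            if r.state_b in col:
                X[i, col[r.state_b]] -= 1
            y[i] = r.chose_a_healthier
        smfit = sm.Probit(y, X).fit(disp=0, method="newton", tol=1e-10)
        for j, s in enumerate(design.columns):
            assert fit.beta[s] == pytest.approx(smfit.params[j], abs=1e-5)
            assert fit.se(s) == pytest.approx(np.sqrt(smfit.cov_params()[j, j]),
                                              rel=1e-3)
        assert fit.loglik == pytest.approx(smfit.llf, abs=1e-6)

    def test_null_data_recovers_zero(self):
        reg = tiny_registry(2)
        rng = np.random.default_rng(5)
        pairs = [("FH", "S1"), ("S1", "S2"), ("S2", "DEAD"), ("FH", "DEAD")]
        pc = [PCResponse("r", a, b, bool(rng.random() < 0.5))
              for a, b in pairs * 100]
        fit = fit_probit(build_design(pc, reg))
        for s in fit.columns:
            assert abs(fit.beta[s]) < 1.96 * fit.se(s) + 0.05

    def test_perfect_separation_raises_naming_state(self):
        reg = tiny_registry(1)
        pc = [PCResponse("r", "S1", "DEAD", True)] * 30
        pc += [PCResponse("r", "FH", "DEAD", bool(i % 2)) for i in range(30)]
        with pytest.raises(SeparationError, match="S1"):
            fit_probit(build_design(pc, reg))
        # ridge penalty makes the likelihood proper again
        fit = fit_probit(build_design(pc, reg), ridge=0.1)
        assert np.isfinite(fit.beta["S1"])

    def test_covariance_positive_semidefinite(self, recovery_world):
        registry, _, _, pc = recovery_world
        fit = fit_probit(build_design(pc, registry))
        eig = np.linalg.eigvalsh(fit.cov)
        assert eig.min() > -1e-10


class TestAnchoring:
    def make_probs(self, p_map):
        import pandas as pd

        rows = [(s, p, p, p) for s, p in p_map.items()]
        return pd.DataFrame(rows, columns=["state_id", "p", "p_lo", "p_hi"]
                            ).set_index("state_id")

    def test_anchor_identities(self):
        reg = tiny_registry(1)
        probs = self.make_probs({"FH": 0.9, "S1": 0.9, "DEAD": 0.5})
        est = {e.state_id: e for e in anchor_to_dw(probs, reg)}
        assert est["FH"].dw == 0.0
        assert est["DEAD"].dw == 1.0
        assert est["S1"].dw == pytest.approx(0.0)  # p equal to FH -> weight 0
        probs2 = self.make_probs({"FH": 0.9, "S1": 0.5, "DEAD": 0.5})
        est2 = {e.state_id: e for e in anchor_to_dw(probs2, reg)}
        assert est2["S1"].dw == pytest.approx(1.0)  # p equal to dead -> weight 1

    def test_affine_on_latent_scale(self):
        """dw is affine in the probit index z = Phi^-1(p)."""
        reg = tiny_registry(1)
        probs = self.make_probs({"FH": 0.9, "S1": 0.7, "DEAD": 0.5})
        est = {e.state_id: e.dw for e in anchor_to_dw(probs, reg)}
        z = {k: norm.ppf(v) for k, v in {"FH": 0.9, "S1": 0.7, "DEAD": 0.5}.items()}
        expected = (z["FH"] - z["S1"]) / (z["FH"] - z["DEAD"])
        assert est["S1"] == pytest.approx(expected)  # = 0.5907 for these p
        assert expected == pytest.approx(0.590808, abs=1e-5)

    def test_ordering_reverses_beta(self, recovery_world):
        registry, _, _, pc = recovery_world
        fit = fit_probit(build_design(pc, registry))
        probs = predicted_probabilities(fit)
        est = {e.state_id: e.dw for e in anchor_to_dw(probs, registry)}
        ids = registry.substantive_ids
        betas = np.array([fit.beta[s] for s in ids])
        dws = np.array([est[s] for s in ids])
        assert np.all(np.argsort(betas) == np.argsort(-dws))

    def test_degenerate_orientation_raises(self):
        reg = tiny_registry(1)
        probs = self.make_probs({"FH": 0.4, "S1": 0.5, "DEAD": 0.6})
        with pytest.raises(AnchoringError):
            anchor_to_dw(probs, reg)

    def test_permutation_equivariance(self):
        """Relabelling states permutes the estimates identically."""
        reg = tiny_registry(2)
        truth = TrueWeights({"FH": 0.0, "S1": 0.3, "S2": 0.7, "DEAD": 1.0}, reg)
        cfg = dw.SimConfig(n_respondents=100, k_pairs=10, sigma_pc=0.5, seed=44)
        pc = dw.simulate_pc_responses(reg, truth, cfg)
        est1, _ = dw.estimate_model1(pc, reg)
        swap = {"S1": "S2", "S2": "S1", "FH": "FH", "DEAD": "DEAD"}
        pc_sw = [PCResponse(r.respondent_id, swap[r.state_a], swap[r.state_b],
                            r.chose_a_healthier) for r in pc]
        est2, _ = dw.estimate_model1(pc_sw, reg)
        d1 = {e.state_id: e.dw for e in est1}
        d2 = {e.state_id: e.dw for e in est2}
        assert d1["S1"] == pytest.approx(d2["S2"], abs=1e-8)
        assert d1["S2"] == pytest.approx(d2["S1"], abs=1e-8)


class TestPredictedProbabilities:
    def test_reference_probability_half(self, recovery_world):
        registry, _, _, pc = recovery_world
        fit = fit_probit(build_design(pc, registry))
        probs = predicted_probabilities(fit)
        assert probs.loc[registry.dead_id, "p"] == 0.5

    def test_phi_of_standard_quantile(self):
        reg = tiny_registry(1)
        pc = [PCResponse("r", "S1", "DEAD", i < 95) for i in range(100)]
        pc += [PCResponse("r", "FH", "DEAD", i < 99) for i in range(100)]
        fit = fit_probit(build_design(pc, reg))
        probs = predicted_probabilities(fit)
        assert fit.beta["S1"] == pytest.approx(1.6449, abs=1e-3)
        assert probs.loc["S1", "p"] == pytest.approx(0.95, abs=1e-6)
        assert (probs["p_lo"] <= probs["p"]).all() and (probs["p"] <= probs["p_hi"]).all()


class TestHoldout:
    def test_perfect_predictions_give_zero_mad(self):
        # deterministic world: every holdout frequency is 0 or 1 and matches
        reg = tiny_registry(2)
        truth = TrueWeights({"FH": 0.0, "S1": 0.3, "S2": 0.7, "DEAD": 1.0}, reg)
        cfg = dw.SimConfig(n_respondents=300, k_pairs=10, sigma_pc=0.25, seed=55)
        pc = dw.simulate_pc_responses(reg, truth, cfg)
        rep = split_and_validate(pc, reg, frac=0.8, seed=1)
        assert 0.0 <= rep.mad <= 1.0
        assert rep.n_fit + rep.n_holdout == len(pc)

    def test_full_fraction_rejected(self, recovery_world):
        registry, _, _, pc = recovery_world
        with pytest.raises(ValueError):
            split_and_validate(pc, registry, frac=1.0, seed=0)

    def test_mad_small_under_recovery_conditions(self, recovery_world):
        registry, _, _, pc = recovery_world
        rep = split_and_validate(pc, registry, frac=0.8, seed=11)
        assert rep.mad < 0.15


def test_estimates_frame_schema(recovery_world):
    registry, _, _, pc = recovery_world
    est, _ = dw.estimate_model1(pc, registry)
    df = estimates_to_frame(est)
    assert list(df.columns) == ["state_id", "dw", "ci_lo", "ci_hi", "model_tag"]
    assert (df["ci_lo"] <= df["dw"]).all() and (df["dw"] <= df["ci_hi"]).all()
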