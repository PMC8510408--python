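"""Regular-solution theory: Clint baseline, composition solver, beta."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilemix import (
    BinaryMixtureMeasurement,
    PureSurfactantRecord,
    analyze_mixtures,
    classify_interaction,
    clint_cmc,
    compute_beta,
    predict_mixed_cmc,
    solve_micellar_composition,
)
from bilemix.errors import DomainError, NoPhysicalRootError


def oracle_residual(x1, alpha, c12, c1, c2):
    """Defining equation written out independently of the solver."""
    return x1**2 * np.log(alpha * c12 / (x1 * c1)) - (1 - x1) ** 2 * np.log(
        (1 - alpha) * c12 / ((1 - x1) * c2)
    )


class TestClint:
    @pytest.mark.parametrize(
        "alpha, c1, c2, expected",
        [
            (0.5, 4.0, 4.0, 4.0),  # equal components, any alpha
            (0.2, 4.0, 4.0, 4.0),
            (1.0, 13.0, 6.0, 13.0),  # boundary reduces to pure component
            (0.0, 13.0, 6.0, 6.0),
            (0.2, 13.0, 6.0, 1.0 / (0.2 / 13 + 0.8 / 6)),  # 6.7241 mM
        ],
    )
    def test_values(self, alpha, c1, c2, expected):
        assert clint_cmc(alpha, c1, c2) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("c1, c2", [(-1.0, 5.0), (5.0, 0.0)])
    def test_nonpositive_concentration_rejected(self, c1, c2):
        with pytest.raises(DomainError):
            clint_cmc(0.5, c1, c2)


class TestMicellarComposition:
    def test_symmetric_mixture_splits_evenly(self):
        m = BinaryMixtureMeasurement(alpha=0.5, cmc_mix=5.0, cmc_1=5.0, cmc_2=5.0)
        assert solve_micellar_composition(m) == pytest.approx(0.5, abs=1e-10)

    def test_ideal_mixture_matches_closed_form(self):
        # at beta=0 the micellar composition is x1 = alpha*C12/C1
        alpha, c1, c2 = 0.2, 13.0, 6.0
        c12 = clint_cmc(alpha, c1, c2)
        m = BinaryMixtureMeasurement(alpha=alpha, cmc_mix=c12, cmc_1=c1, cmc_2=c2)
        assert solve_micellar_composition(m) == pytest.approx(
            alpha * c12 / c1, abs=1e-9
        )

    def test_forward_inverse_round_trip(self):
        c12, x1_true = predict_mixed_cmc(0.3, 10.0, 5.0, -2.0)
        m = BinaryMixtureMeasurement(alpha=0.3, cmc_mix=c12, cmc_1=10.0, cmc_2=5.0)
        assert solve_micellar_composition(m) == pytest.approx(x1_true, abs=1e-8)

    def test_inconsistent_cmc_triple_raises(self):
        # a mixed CMC between the lopsided pure CMCs that no composition
        # can reconcile: the defining residual never changes sign
        m = BinaryMixtureMeasurement(alpha=0.5, cmc_mix=50.0, cmc_1=1.0, cmc_2=100.0)
        with pytest.raises(NoPhysicalRootError):
            solve_micellar_composition(m)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        xs = np.linspace(1e-6, 1 - 1e-6, 100_001)
        for _ in range(10):
            alpha = rng.uniform(0.1, 0.9)
            c1, c2 = rng.uniform(0.5, 20, 2)
            beta = rng.uniform(-6, 6)
            c12, _ = predict_mixed_cmc(alpha, c1, c2, beta)
            m = BinaryMixtureMeasurement(
                alpha=alpha, cmc_mix=c12, cmc_1=c1, cmc_2=c2
            )
            x1 = solve_micellar_composition(m)
            grid_x1 = xs[np.argmin(np.abs(oracle_residual(xs, alpha, c12, c1, c2)))]
            assert abs(x1 - grid_x1) < (xs[1] - xs[0])


class TestComputeBeta:
    def test_ideal_mixture_gives_zero_beta(self):
        c12 = clint_cmc(0.35, 9.0, 3.0)
        m = BinaryMixtureMeasurement(alpha=0.35, cmc_mix=c12, cmc_1=9.0, cmc_2=3.0)
        sol = compute_beta(m)
        assert sol.beta == pytest.approx(0.0, abs=1e-6)
        assert sol.label == "ideal"

    @pytest.mark.parametrize("beta_true", [-4.0, -2.0, -0.5, 0.7, 3.0])
    def test_round_trip_recovers_planted_beta(self, beta_true):
        c12, _ = predict_mixed_cmc(0.3, 10.0, 5.0, beta_true)
        m = BinaryMixtureMeasurement(alpha=0.3, cmc_mix=c12, cmc_1=10.0, cmc_2=5.0)
        sol = compute_beta(m)
        assert sol.beta == pytest.approx(beta_true, abs=1e-6)
        assert sol.beta_consistency < 1e-6

    def test_activity_coefficients_consistent(self):
        c12, _ = predict_mixed_cmc(0.6, 8.0, 2.0, 1.5)
        m = BinaryMixtureMeasurement(alpha=0.6, cmc_mix=c12, cmc_1=8.0, cmc_2=2.0)
        sol = compute_beta(m)
        assert sol.f1 == pytest.approx(np.exp(sol.beta * (1 - sol.x1) ** 2))
        assert sol.f2 == pytest.approx(np.exp(sol.beta * sol.x1**2))
        assert sol.residual < 1e-10

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.05, 0.95),
        c1=st.floats(0.5, 20),
        c2=st.floats(0.5, 20),
        beta=st.floats(-8, 8),
    )
    def test_round_trip_property(self, alpha, c1, c2, beta):
        c12, _ = predict_mixed_cmc(alpha, c1, c2, beta)
        m = BinaryMixtureMeasurement(alpha=alpha, cmc_mix=c12, cmc_1=c1, cmc_2=c2)
        assert compute_beta(m).beta == pytest.approx(beta, abs=1e-6)


class TestPredictMixedCmc:
    def test_zero_beta_reduces_to_clint(self):
        c12, _ = predict_mixed_cmc(0.4, 12.0, 3.0, 0.0)
        assert c12 == pytest.approx(clint_cmc(0.4, 12.0, 3.0), abs=1e-9)

    def test_symmetric_composition_for_any_beta(self):
        for beta in (-5.0, -1.0, 0.0, 2.0, 6.0):
            _, x1 = predict_mixed_cmc(0.5, 7.0, 7.0, beta)
            assert x1 == pytest.approx(0.5, abs=1e-9)

    def test_mixed_cmc_monotone_in_beta(self):
        betas = np.linspace(-6, 6, 49)
        cmcs = [predict_mixed_cmc(0.3, 10.0, 5.0, b)[0] for b in betas]
        assert np.all(np.diff(cmcs) > 0)
        # synergism lowers the mixed CMC below the ideal baseline
        assert cmcs[0] < clint_cmc(0.3, 10.0, 5.0) < cmcs[-1]

    def test_boundary_alpha_rejected(self):
        with pytest.raises(DomainError):
            predict_mixed_cmc(0.0, 10.0, 5.0, -1.0)


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "beta, expected",
        [
            (1.33, "antagonistic"),  # NaC/NaTC at alpha=0.2
            (-0.40, "synergistic"),  # NaC/NaDC at alpha=0.2
            (0.0, "ideal"),
            (0.04, "ideal"),  # below the default ideality threshold
        ],
    )
    def test_labels(self, beta, expected):
        assert classify_interaction(beta) == expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(DomainError):
            classify_interaction(1.0, tol=-0.1)


class TestRecordsAndBatch:
    def test_pure_record_validation(self):
        with pytest.raises(DomainError):
            PureSurfactantRecord("NaC", "XX", 11.0, 298.15)
        with pytest.raises(DomainError):
            PureSurfactantRecord("NaC", "PU", -1.0, 298.15)

    def test_mixture_validation(self):
        with pytest.raises(DomainError):
            BinaryMixtureMeasurement(alpha=1.2, cmc_mix=5.0, cmc_1=5.0, cmc_2=5.0)

    def test_analyze_mixtures_flags_inconsistent_rows(self):
        good_c12, _ = predict_mixed_cmc(0.4, 10.0, 5.0, -1.0)
        rows = [
            BinaryMixtureMeasurement(alpha=0.4, cmc_mix=good_c12, cmc_1=10.0, cmc_2=5.0),
            BinaryMixtureMeasurement(alpha=0.5, cmc_mix=50.0, cmc_1=1.0, cmc_2=100.0),
        ]
        df = analyze_mixtures(rows)
        assert df.loc[0, "beta"] == pytest.approx(-1.0, abs=1e-6)
        assert df.loc[1, "label"] == "no-physical-root"
        assert np.isnan(df.loc[1, "beta"])
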