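"""Forward branching process: label means, offspring matrix, PGFs, fixed point."""

import numpy as np
import pytest

from seqepi import degrees as dg
from seqepi import immunity as imm
from seqepi.first_epidemic import first_outbreak, solve_q_tilde
from seqepi.forward import (
    R0_second,
    forward_pgfs,
    label_means,
    major_outbreak_probability,
    offspring_matrix,
    second_epidemic_forward,
    solve_fixed_point,
)

from numdiff import jacobian_at_ones

P1 = 0.15
MODELS = {
    "polarized": imm.polarized(0.3, 0.5),
    "leaky": imm.leaky_multiplicative(0.3, np.sqrt(0.5), np.sqrt(0.5)),
}


class TestLabelMeans:
    def test_cubic_network_closed_forms(self):
        # P(D=3)=1, p=3/4: (mu_AA, mu_AB, mu_BA, mu_BB) = (11/6, 1/6, 4/3, 2/3)
        lm = label_means(dg.constant(3), 0.75, 1 / 9)
        assert lm.mu_AA == pytest.approx(11 / 6)
        assert lm.mu_AB == pytest.approx(1 / 6)
        assert lm.mu_BA == pytest.approx(4 / 3)
        assert lm.mu_BB == pytest.approx(2 / 3)

    @pytest.mark.parametrize("p", [0.6, 0.75, 0.9])
    def test_cubic_network_generic_p(self, p):
        lm = label_means(dg.constant(3), p, solve_q_tilde(dg.constant(3), p))
        assert lm.mu_AA == pytest.approx(2 * (1 - (1 - p) ** 2 / p), abs=1e-9)
        assert lm.mu_AB == pytest.approx(2 * (1 - p) ** 2 / p, abs=1e-9)
        assert lm.mu_BA == pytest.approx(2 * (2 * p - 1) / p, abs=1e-9)
        assert lm.mu_BB == pytest.approx(2 * (1 - p) / p, abs=1e-9)

    def test_certain_transmission_limit(self):
        # p = 1: x* = 0, so the label-B means involving f''(0) vanish
        # (label B has probability zero; B rows use the sterile convention)
        lm = label_means(dg.constant(3), 1.0, 0.0)
        assert lm.mu_AA == pytest.approx(2.0)
        assert lm.mu_AB == 0.0
        assert lm.mu_BB == 0.0

    @pytest.mark.parametrize("name", ["constant", "poisson", "geometric", "powerlaw"])
    def test_shared_factor_identity(self, study_distributions, name):
        d = study_distributions[name]
        qt = solve_q_tilde(d, P1)
        lm = label_means(d, P1, qt)
        assert lm.mu_BA * qt == pytest.approx(
            (1 - P1) * (1 - qt) * lm.mu_BB, rel=1e-12
        )

    def test_requires_supercritical(self):
        with pytest.raises(ValueError):
            label_means(dg.constant(10), 0.05, 1.0)


class TestOffspringMatrix:
    def test_structure(self, study_distributions):
        d = study_distributions["poisson"]
        lm = label_means(d, P1, solve_q_tilde(d, P1))
        M = offspring_matrix(lm, MODELS["leaky"], P1)
        assert M[2, 1] == 0.0
        assert (M >= 0).all()

    def test_zero_table_gives_zero_matrix(self, study_distributions):
        d = study_distributions["constant"]
        lm = label_means(d, P1, solve_q_tilde(d, P1))
        M = offspring_matrix(lm, imm.general(0, 0, 0, 0), P1)
        assert (M == 0).all()
        assert R0_second(M) == 0.0

    def test_complete_immunity_reduces_to_single_type(self, study_distributions):
        # pi_11 = pi_01 = 0: the second epidemic lives among escapees only
        for d in study_distributions.values():
            lm = label_means(d, P1, solve_q_tilde(d, P1))
            M = offspring_matrix(lm, imm.general(0.3, 0.0, 0.2, 0.0), P1)
            assert R0_second(M) == pytest.approx(0.3 * lm.mu_BB, abs=1e-12)


class TestForwardPGFs:
    @pytest.mark.parametrize("name", ["constant", "poisson", "geometric", "powerlaw"])
    @pytest.mark.parametrize("model", list(MODELS))
    def test_normalisation_at_ones(self, study_distributions, name, model):
        d = study_distributions[name]
        fe = first_outbreak(d, P1)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, MODELS[model])
        for f in (b.fY1, b.fY3, b.fYt1, b.fYt2, b.fYt3, b.f1, b.f3, b.ft1, b.ft2, b.ft3):
            assert f(1.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-10)

    def test_cubic_network_type3_pgf_closed_form(self):
        # f_Y-tilde-3(s) = f_{D-tilde-1}((1-p)(1-qt)s1 + qt s3)/qt
        #                = 9((2/9)s1 + (1/9)s3)^2 for P(D=3)=1, p=3/4
        d = dg.constant(3)
        fe = first_outbreak(d, 0.75)
        b = forward_pgfs(d, 0.75, fe.q_tilde, fe.q, imm.polarized(0.3, 0.5))
        for s1, s3 in [(0.2, 0.9), (0.0, 1.0), (1.0, 0.0), (0.5, 0.5)]:
            assert b.fYt3(s1, 0.77, s3) == pytest.approx(
                9 * (2 / 9 * s1 + 1 / 9 * s3) ** 2, abs=1e-9
            )

    @pytest.mark.parametrize("name", ["constant", "poisson", "geometric", "powerlaw"])
    @pytest.mark.parametrize("model", list(MODELS))
    def test_jacobian_matches_offspring_matrix(self, study_distributions, name, model):
        # the central consistency check tying the PGFs to the mean matrix;
        # adjudicates the mu_AB prefactor
        d = study_distributions[name]
        fe = first_outbreak(d, P1)
        im = MODELS[model]
        lm = label_means(d, P1, fe.q_tilde)
        M = offspring_matrix(lm, im, P1)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, im)
        assert np.allclose(jacobian_at_ones(b.ft), M, atol=1e-6)


class TestFixedPoint:
    def test_subcritical_is_all_ones(self, study_distributions):
        d = study_distributions["constant"]
        fe = first_outbreak(d, P1)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, imm.polarized(0.05, 0.5))
        xi = solve_fixed_point(b.ft)
        assert np.allclose(xi, 1.0, atol=1e-9)

    @pytest.mark.parametrize("name", ["constant", "geometric"])
    def test_residual_and_minimality(self, study_distributions, name):
        d = study_distributions[name]
        fe = first_outbreak(d, P1)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, MODELS["polarized"])
        xi = solve_fixed_point(b.ft)
        assert np.max(np.abs(xi - b.ft(xi))) < 1e-11
        # iterating from another sub-fixed-point start reaches the same limit
        s = np.full(3, 0.05)
        for _ in range(100_000):
            s_next = b.ft(s)
            if np.max(np.abs(s_next - s)) < 1e-13:
                break
            s = s_next
        assert np.allclose(s, xi, atol=1e-9)

    def test_all_pi_zero_never_spreads(self, study_distributions):
        d = study_distributions["poisson"]
        fe = first_outbreak(d, P1)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, imm.general(0, 0, 0, 0))
        xi = solve_fixed_point(b.ft)
        assert np.allclose(xi, 1.0)
        assert major_outbreak_probability(b, xi, fe.q, "uniform") == pytest.approx(
            0.0, abs=1e-12
        )


class TestOutbreakProbability:
    def test_table_values_weighted_seeding(self, study_distributions):
        sol = second_epidemic_forward(
            study_distributions["constant"], P1, MODELS["polarized"]
        )
        assert sol.p_major_weighted == pytest.approx(0.8720, abs=5e-5)
        sol = second_epidemic_forward(
            study_distributions["poisson"], P1, MODELS["leaky"]
        )
        assert sol.p_major_weighted == pytest.approx(0.8053, abs=5e-5)

    def test_weighted_seeding_undefined_for_general_table(self, study_distributions):
        sol = second_epidemic_forward(
            study_distributions["constant"], P1, imm.general(0.3, 0.1, 0.2, 0.15)
        )
        assert sol.p_major_weighted is None
        assert 0.0 <= sol.p_major_uniform <= 1.0

    def test_single_status_reductions_match_smaller_processes(self, study_distributions):
        # (pi_11 only) and (pi_00 only) collapse onto single-type processes
        # on the prior-case / escapee sub-populations; check against a
        # directly coded scalar fixed point
        d = study_distributions["geometric"]
        fe = first_outbreak(d, P1)
        lm = label_means(d, P1, fe.q_tilde)

        # escapee-only: offspring PGF g(s) = fYt3 evaluated with thinning
        im = imm.general(0.35, 0.0, 0.0, 0.0)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, im)
        g = lambda s: b.fYt3(1.0, 1.0, 1 - 0.35 + 0.35 * s)
        s = 0.0
        for _ in range(100_000):
            s2 = g(s)
            if abs(s2 - s) < 1e-14:
                break
            s = s2
        xi = solve_fixed_point(b.ft)
        assert xi[2] == pytest.approx(s, abs=1e-8)
        p_direct = 1.0 - (1 - fe.q) * 1.0 - fe.q * b.fY3(1.0, 1.0, 1 - 0.35 + 0.35 * s)
        assert major_outbreak_probability(b, xi, fe.q, "uniform") == pytest.approx(
            p_direct, abs=1e-8
        )

        # prior-case-only: types 1, 2 form a closed two-type system and
        # type-3 individuals never transmit (xi_3 = 1)
        im = imm.general(0.0, 0.0, 0.0, 0.35)
        b = forward_pgfs(d, P1, fe.q_tilde, fe.q, im)
        t = lambda x: 1 - 0.35 + 0.35 * x
        s1 = s2 = 0.0
        for _ in range(100_000):
            n1 = b.fYt1(t(s1), t(s2), 1.0)
            n2 = b.fYt2(t(s1), t(s2), 1.0)
            if max(abs(n1 - s1), abs(n2 - s2)) < 1e-14:
                break
            s1, s2 = n1, n2
        xi = solve_fixed_point(b.ft)
        assert xi[2] == pytest.approx(1.0, abs=1e-12)
        assert xi[0] == pytest.approx(s1, abs=1e-8)
        assert xi[1] == pytest.approx(s2, abs=1e-8)
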