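"""Variational principle: objective, optimization, partition form, envelopes."""

from fractions import Fraction as F

import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifvar import (
    bf_max,
    bf_value,
    enumerate_connected_motifs,
    exponent_function,
    grid_oracle,
    objective_value,
    optimize,
    parse_motif_spec,
)
from motifvar.piecewise import LinearExponent
from motifvar.variational import typical_values

TAUS = [F(21, 10), F(11, 5), F(5, 2), F(14, 5), F(29, 10)]


class TestObjective:
    def test_triangle_all_half(self):
        t = parse_motif_spec("triangle")
        assert objective_value(t, [F(1, 2)] * 3, F(5, 2)) == F(-9, 4)
        # count exponent 3 - 9/4 = 3(3-tau)/2 at tau=5/2
        assert 3 + F(-9, 4) == F(3, 4)

    @pytest.mark.parametrize("tau", TAUS)
    def test_wedge_center_hub(self, tau):
        w = parse_motif_spec("wedge")
        assert objective_value(w, [0, 1, 0], tau) == 1 - tau

    def test_triangle_all_zero(self):
        t = parse_motif_spec("triangle")
        assert objective_value(t, [0, 0, 0], F(5, 2)) == -3

    def test_bounds_enforced(self):
        t = parse_motif_spec("triangle")
        with pytest.raises(ValueError):
            objective_value(t, [F(3, 2), 0, 0], F(5, 2))
        with pytest.raises(ValueError):
            objective_value(t, [1, 0, 0], F(5, 2), mode="typical")  # 1 > 1/(tau-1)
        with pytest.raises(ValueError):
            objective_value(t, [0, 0, 0], F(7, 2))


class TestOptimize:
    def test_triangle_unique_all_half(self):
        r = optimize(parse_motif_spec("triangle"), F(5, 2))
        assert r.optimal_value == F(-9, 4)
        assert r.count_exponent == F(3, 4)
        assert r.bf_value == 0
        assert not r.degenerate and not r.log_flag
        assert r.optimizers == ((F(1, 2),) * 3,)

    def test_diamond_degenerate_face(self):
        r = optimize(parse_motif_spec("diamond"), F(5, 2))
        assert r.optimal_value == 2 * (1 - F(5, 2))
        assert r.count_exponent == 6 - 2 * F(5, 2)
        assert r.degenerate and r.log_flag
        assert r.face_dimension == 1
        assert all(role == "pair-constrained" for _, role in r.vertex_roles)

    def test_claw_typical_center_at_cutoff(self):
        tau = F(5, 2)
        r = optimize(parse_motif_spec("claw"), tau, mode="typical")
        assert r.count_exponent == 3 / (tau - 1) == 2
        assert r.optimizers == ((F(2, 3), F(0), F(0), F(0)),)
        free = optimize(parse_motif_spec("claw"), tau)
        assert free.count_exponent == 5 - tau
        assert r.count_exponent < free.count_exponent

    @pytest.mark.parametrize("tau", TAUS)
    def test_typical_below_free(self, tau):
        for m in enumerate_connected_motifs(4):
            typ = optimize(m, tau, mode="typical")
            free = optimize(m, tau, mode="free")
            assert typ.count_exponent <= free.count_exponent
            uses_hub = any(F(1) in opt for opt in free.optimizers)
            if not uses_hub:
                assert typ.count_exponent == free.count_exponent

    def test_count_exponent_positive(self, catalog_all):
        for m in catalog_all:
            for tau in (F(21, 10), F(29, 10)):
                r = optimize(m, tau)
                assert r.count_exponent > 0
                assert r.bf_value >= 0


class TestPartitionForm:
    def test_triangle_all_s3_zero(self):
        assert bf_value(parse_motif_spec("triangle"), [3, 3, 3], F(5, 2)) == 0

    def test_bowtie_center_hub_partition(self):
        # center in S2, four leaves in S1: 3 - 4/(tau-1)
        tau = F(5, 2)
        bt = parse_motif_spec("bowtie")  # vertex 0 is the center
        val = bf_value(bt, {0: 2, 1: 1, 2: 1, 3: 1, 4: 1}, tau)
        assert val == 3 - 4 / (tau - 1) == F(1, 3)
        # via the count identity: 5(3-tau)/2 + (tau-1) Bf/2 = 4 - tau
        assert 5 * (3 - tau) / 2 + (tau - 1) * val / 2 == 4 - tau

    @pytest.mark.parametrize("tau", TAUS)
    def test_claw_partition(self, tau):
        claw = parse_motif_spec("claw")
        assert bf_value(claw, {0: 2, 1: 1, 2: 1, 3: 1}, tau) == 2

    def test_requires_complete_partition(self):
        with pytest.raises(ValueError):
            bf_value(parse_motif_spec("triangle"), [1, 2], F(5, 2))

    @pytest.mark.parametrize("tau", TAUS)
    def test_identity_with_objective_maximum(self, tau):
        """k + max f = (3-tau)k/2 + (tau-1) B_f/2, exact, on the 4-vertex catalog."""
        for m in enumerate_connected_motifs(4):
            r = optimize(m, tau)
            lhs = m.k + r.optimal_value
            rhs = (3 - tau) * m.k / 2 + (tau - 1) * bf_max(m, tau) / 2
            assert lhs == rhs


class TestExponentFunction:
    def test_triangle_single_piece(self):
        env = exponent_function(parse_motif_spec("triangle"))
        assert env.interior_breakpoints == []
        assert env.segments == [LinearExponent(F(9, 2), F(-3, 2))]

    def test_bowtie_two_pieces(self):
        env = exponent_function(parse_motif_spec("bowtie"))
        assert env.interior_breakpoints == [F(7, 3)]
        assert env.segments == [
            LinearExponent(F(15, 2), F(-5, 2)),
            LinearExponent(F(4), F(-1)),
        ]

    def test_wedge_single_piece(self):
        env = exponent_function(parse_motif_spec("wedge"))
        assert env.segments == [LinearExponent(F(4), F(-1))]

    @pytest.mark.parametrize("tau", TAUS)
    def test_envelope_matches_pointwise_optimum(self, tau, catalog_all):
        for m in catalog_all:
            assert exponent_function(m)(tau) == optimize(m, tau).count_exponent

    @pytest.mark.parametrize("tau", TAUS)
    def test_typical_envelope_matches_pointwise(self, tau):
        for m in enumerate_connected_motifs(4):
            env = exponent_function(m, mode="typical")
            assert env(tau) == optimize(m, tau, mode="typical").count_exponent

    def test_square_motif_equals_graphlet_sum_identity(self):
        """Counting square motifs = counting square+diamond+K4 graphlets: the
        motif envelope is the max of the three graphlet envelopes (6 - 2 tau,
        degenerate -> one log factor)."""
        sq_motif = exponent_function(parse_motif_spec("square"), variant="motif")
        parts = [
            exponent_function(parse_motif_spec(name), variant="graphlet")
            for name in ("square", "diamond", "k4")
        ]
        for tau in TAUS:
            assert sq_motif(tau) == max(p(tau) for p in parts)
            assert sq_motif(tau) == 6 - 2 * tau
        assert sq_motif.meta[0]["degenerate"]


class TestGridOracle:
    def test_triangle_matches_optimize(self):
        t = parse_motif_spec("triangle")
        assert grid_oracle(t, F(5, 2), step=F(1, 10)) == F(-9, 4)

    def test_diamond_tied_grid_argmax_shows_face(self):
        val, args = grid_oracle(
            parse_motif_spec("diamond"), F(5, 2), step=F(1, 4), return_argmax=True
        )
        assert val == -3
        # the optimal face beta, beta, 1-beta, 1-beta sampled at beta in {1/2,3/4,1}
        assert len(args) == 3

    @given(st.sampled_from([F(21, 10), F(5, 2), F(14, 5)]),
           st.sampled_from(["free", "typical"]))
    def test_grid_never_beats_candidates_k4(self, tau, mode):
        for m in enumerate_connected_motifs(4):
            g = grid_oracle(m, tau, mode=mode, step=F(1, 6))
            assert g <= optimize(m, tau, mode=mode).optimal_value

    def test_typical_values_are_ordered(self):
        vals = typical_values(F(5, 2))
        assert vals == (F(0), F(1, 3), F(1, 2), F(2, 3))
        assert list(vals) == sorted(vals)
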