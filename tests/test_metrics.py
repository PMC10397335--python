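"""Ground-truth/PIV comparison statistics and characteristic scales."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pivbench import (
    AgentState, MetricUndefinedError, PIVField, VicsekParams,
    alignment_score, characteristic_radius, coherence_difference,
    gamma0, init_state, local_order, local_order_piv, order_parameter, r0,
)

P = VicsekParams()  # L=5, 615 px


def make_field(anchors, vectors, t=0, valid=None, grid_px=64):
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = len(anchors)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return PIVField(
        t=t, anchors=anchors, vectors=vectors,
        peak_corr=np.ones(n), valid=np.asarray(valid, dtype=bool),
        lattice_shape=(1, n), grid_px=grid_px,
    )


def random_state_and_field(seed, n_agents=40, n_vec=9):
    r = np.random.default_rng(seed)
    state = AgentState(0, r.uniform(0, P.L, (n_agents, 2)),
                       r.uniform(0, 2 * np.pi, n_agents))
    anchors = r.uniform(0, P.gamma_img, (n_vec, 2))
    vectors = r.normal(0, 3, (n_vec, 2))
    return state, make_field(anchors, vectors)


class TestOrderParameter:
    def test_aligned_state_is_one(self):
        s = AgentState(0, np.zeros((5, 2)), np.full(5, 1.1))
        assert order_parameter(s) == pytest.approx(1.0)

    def test_antiparallel_pair_cancels(self):
        s = AgentState(0, np.zeros((2, 2)), [0.0, np.pi])
        assert order_parameter(s) == pytest.approx(0.0, abs=1e-12)

    def test_hand_vector_sum(self):
        # headings 0, pi/2, pi/2, pi/2 -> |(1, 3)|/4 = sqrt(10)/4
        s = AgentState(0, np.zeros((4, 2)), [0.0, np.pi / 2, np.pi / 2, np.pi / 2])
        assert order_parameter(s) == pytest.approx(np.sqrt(10) / 4)

    def test_zero_speed_undefined(self):
        s = AgentState(0, np.zeros((2, 2)), [0.0, 1.0])
        with pytest.raises(MetricUndefinedError):
            order_parameter(s, v0=0.0)


class TestLocalOrder:
    def test_single_enclosed_agent(self):
        s = AgentState(0, [[1.0, 1.0]], [0.3])
        per, mean = local_order(s, [[123.0, 123.0]], 30.0, P)
        assert per[0] == pytest.approx(1.0) and mean == pytest.approx(1.0)

    def test_antiparallel_pair_in_circle(self):
        s = AgentState(0, [[1.0, 1.0], [1.01, 1.0]], [0.0, np.pi])
        _, mean = local_order(s, [[123.0, 123.0]], 30.0, P)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_mean_over_centers_excludes_empty(self):
        s = AgentState(0, [[1.0, 1.0], [1.01, 1.0], [3.0, 3.0]],
                       [0.0, np.pi, 0.5])
        centers = [[123.0, 123.0], [369.0, 369.0], [123.0, 430.0]]
        per, mean = local_order(s, centers, 20.0, P)
        assert per[0] == pytest.approx(0.0, abs=1e-12)
        assert per[1] == pytest.approx(1.0)
        assert np.isnan(per[2])          # empty circle: excluded, not zero
        assert mean == pytest.approx(0.5)

    def test_all_empty_raises(self):
        s = AgentState(0, [[1.0, 1.0]], [0.0])
        with pytest.raises(MetricUndefinedError):
            local_order(s, [[400.0, 400.0]], 5.0, P)


class TestAlignmentScore:
    def test_parallel_agents_give_unity(self):
        s = AgentState(0, [[1.0, 1.0], [1.05, 1.0]], [0.0, 0.0])
        fld = make_field([[123.0, 123.0]], [[2.5, 0.0]])
        assert alignment_score(fld, s, 30.0, P) == pytest.approx(1.0)

    def test_antiparallel_agents_give_minus_one(self):
        s = AgentState(0, [[1.0, 1.0], [1.05, 1.0]], [np.pi, np.pi])
        fld = make_field([[123.0, 123.0]], [[2.5, 0.0]])
        assert alignment_score(fld, s, 30.0, P) == pytest.approx(-1.0)

    def test_hand_cosine_average(self):
        # vector (1,0); enclosed velocities (0,1) and (1,0): (0 + 1)/2
        s = AgentState(0, [[1.0, 1.0], [1.05, 1.0]], [np.pi / 2, 0.0])
        fld = make_field([[123.0, 123.0]], [[1.0, 0.0]])
        assert alignment_score(fld, s, 30.0, P) == pytest.approx(0.5)

    def test_vectors_with_no_agents_are_excluded(self):
        s = AgentState(0, [[1.0, 1.0]], [0.0])
        fld = make_field([[123.0, 123.0], [400.0, 400.0]],
                         [[1.0, 0.0], [-1.0, 0.0]])
        # the second vector's circle is empty; it must not drag A^R down
        assert alignment_score(fld, s, 30.0, P) == pytest.approx(1.0)

    def test_no_participating_vectors_raises(self):
        s = AgentState(0, [[1.0, 1.0]], [0.0])
        fld = make_field([[400.0, 400.0]], [[1.0, 0.0]])
        with pytest.raises(MetricUndefinedError):
            alignment_score(fld, s, 5.0, P)

    def test_time_index_mismatch_rejected(self):
        s = AgentState(3, [[1.0, 1.0]], [0.0])
        fld = make_field([[123.0, 123.0]], [[1.0, 0.0]], t=2)
        with pytest.raises(ValueError, match="time index"):
            alignment_score(fld, s, 30.0, P)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_scalar_double_loop(self, seed):
        state, fld = random_state_and_field(seed)
        R = 80.0
        period = P.L * P.px_per_unit
        pos = state.pos * P.px_per_unit
        w = state.heading_vectors()
        per_j = []
        for j in range(len(fld.anchors)):
            if not fld.valid[j]:
                continue
            vj = fld.vectors[j]
            nv = np.hypot(*vj)
            if nv == 0:
                continue
            acc, cnt = 0.0, 0
            for i in range(state.n):
                d = fld.anchors[j] - pos[i]
                d -= period * np.round(d / period)
                if d @ d <= R * R:
                    acc += float(vj @ w[i]) / nv
                    cnt += 1
            if cnt:
                per_j.append(acc / cnt)
        want = float(np.mean(per_j))
        assert alignment_score(fld, state, R, P) == pytest.approx(want, abs=1e-12)


class TestCoherenceDifference:
    def test_fully_aligned_is_zero(self):
        s = AgentState(0, [[1.0, 1.0], [1.05, 1.0]], [0.0, 0.0])
        fld = make_field([[123.0, 123.0]], [[2.0, 0.0]])
        assert coherence_difference(s, fld, 30.0, P) == pytest.approx(0.0, abs=1e-12)

    def test_single_vector_circle_has_unit_piv_order(self):
        # R below the lattice spacing: each circle holds only its own vector,
        # so v_a^{R,PIV} = 1 by definition and D^R = 1 - v_a^{R,SPP}
        s = AgentState(0, [[1.0, 1.0], [1.01, 1.0]], [0.0, np.pi])
        fld = make_field([[123.0, 123.0], [400.0, 123.0]],
                         [[1.0, 0.0], [0.0, 1.0]])
        period = P.L * P.px_per_unit
        _, va_piv = local_order_piv(fld, 30.0, period)
        assert va_piv == pytest.approx(1.0)

    def test_hand_difference(self):
        # one circle: agents antiparallel (v_a^SPP = 0), single own vector
        # (v_a^PIV = 1) -> D^R = 1
        s = AgentState(0, [[1.0, 1.0], [1.01, 1.0]], [0.0, np.pi])
        fld = make_field([[123.0, 123.0]], [[1.0, 0.0]])
        assert coherence_difference(s, fld, 30.0, P) == pytest.approx(1.0)


class TestScales:
    @pytest.mark.parametrize("N,G,g_want,r_want", [
        (100, 615, 61.5, 34.7),
        (300, 615, 35.5, 20.0),
        (1, 615, 615.0, 346.98),
    ])
    def test_printed_values(self, N, G, g_want, r_want):
        assert gamma0(N, G) == pytest.approx(g_want, abs=0.05)
        assert r0(N, G) == pytest.approx(r_want, abs=0.05)

    def test_algebraic_identity(self):
        for N in (7, 100, 300, 2000):
            assert r0(N, 615) * np.sqrt(np.pi) == pytest.approx(gamma0(N, 615))

    def test_strictly_decreasing_in_N(self):
        ns = np.arange(1, 50)
        g = [gamma0(n, 615) for n in ns]
        r = [r0(n, 615) for n in ns]
        assert np.all(np.diff(g) < 0) and np.all(np.diff(r) < 0)

    def test_r0_conventions(self):
        assert characteristic_radius(300, 615, "formula") == pytest.approx(20.0, abs=0.05)
        assert characteristic_radius(300, 615, "grid") == pytest.approx(35.5, abs=0.05)
        with pytest.raises(ValueError):
            characteristic_radius(300, 615, "bogus")


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    def test_metric_ranges(self, seed):
        state, fld = random_state_and_field(seed)
        R = 100.0
        assert 0.0 <= order_parameter(state) <= 1.0
        _, va = local_order(state, fld.anchors, R, P)
        assert 0.0 <= va <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= alignment_score(fld, state, R, P) <= 1.0 + 1e-12
        assert 0.0 <= coherence_difference(state, fld, R, P) <= 1.0 + 1e-12

    @given(st.integers(0, 2**31 - 1),
           st.floats(0.0, 2 * np.pi, allow_nan=False))
    def test_global_rotation_invariance(self, seed, phi):
        state, fld = random_state_and_field(seed)
        R = 100.0
        c, s_ = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s_], [s_, c]])
        state_r = AgentState(0, state.pos, np.mod(state.theta + phi, 2 * np.pi))
        fld_r = make_field(fld.anchors, fld.vectors @ rot.T)
        assert alignment_score(fld_r, state_r, R, P) == pytest.approx(
            alignment_score(fld, state, R, P), abs=1e-9)
        assert order_parameter(state_r) == pytest.approx(
            order_parameter(state), abs=1e-9)
        assert coherence_difference(state_r, fld_r, R, P) == pytest.approx(
            coherence_difference(state, fld, R, P), abs=1e-9)

    def test_uniform_heading_state_has_unit_order(self):
        s = init_state(VicsekParams(N=50, L=2.0), seed=1)
        s.theta[:] = 2.2
        assert order_parameter(s) == pytest.approx(1.0)
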