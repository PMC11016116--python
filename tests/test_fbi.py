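"""Forensic-investigation steps against hand-evaluated oracles."""

import numpy as np
import pytest

from smafbi.core import Bounds, Budget, BestTracker, OptimizerConfig
from smafbi.fbi import (
    investigation_phase,
    pursuit_phase,
    selection_prob,
    step_a1,
    step_a2,
    step_b1,
    step_b2,
)


@pytest.fixture
def bounds10():
    return Bounds.cube(-10.0, 10.0, 1)


def col(*xs):
    return np.array(xs, dtype=float).reshape(-1, 1)


class TestStepA1:
    def test_hand_value(self, bounds10, rng):
        # X_i=4, peers 1 and 3 (midpoint 2), r1=0.75 -> 4 + 0.5*(4-2) = 5
        pos = col(4.0, 1.0, 3.0, 0.0)
        prop = step_a1(pos, 0, bounds10, rng, peers=(1, 2), r1=np.array([0.75]))
        assert prop[0] == pytest.approx(5.0, abs=1e-12)

    def test_zero_displacement_at_midpoint(self, bounds10, rng):
        pos = col(2.0, 1.0, 3.0, 0.0)  # X_i equals the peer midpoint
        for r1 in (0.0, 0.31, 1.0):
            prop = step_a1(pos, 0, bounds10, rng, peers=(1, 2), r1=np.array([r1]))
            assert prop[0] == pytest.approx(2.0, abs=1e-12)

    def test_r1_half_is_identity(self, bounds10, rng):
        pos = col(4.0, 1.0, 3.0, 0.0)
        prop = step_a1(pos, 0, bounds10, rng, peers=(1, 2), r1=np.array([0.5]))
        assert prop[0] == pytest.approx(4.0, abs=1e-12)

    def test_peers_exclude_focal(self, bounds10):
        pos = col(*range(6))
        rng = np.random.default_rng(3)
        for _ in range(200):
            prop = step_a1(pos, 2, bounds10, rng)
            assert np.isfinite(prop).all()


class TestSelectionProb:
    def test_direct_substitution(self):
        assert selection_prob([1.0, 2.0, 3.0]) == pytest.approx([1.0, 0.5, 0.0])

    def test_degenerate_all_equal(self):
        assert selection_prob([7.0, 7.0, 7.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_best_is_one_worst_is_zero(self, rng):
        vals = rng.normal(size=20)
        probs = selection_prob(vals)
        assert probs[np.argmin(vals)] == 1.0
        assert probs[np.argmax(vals)] == 0.0
        assert np.all((probs >= 0.0) & (probs <= 1.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_prob([])


class TestStepA2:
    def test_hand_value(self, bounds10, rng):
        # best=1, X_d=2, X_e=5, X_f=3, r2=0.5 -> 1+2+0.5*2 = 4
        pos = col(0.0, 2.0, 5.0, 3.0)
        prop = step_a2(pos, np.array([1.0]), 0, bounds10, rng,
                       peers=(1, 2, 3), r2=np.array([0.5]))
        assert prop[0] == pytest.approx(4.0, abs=1e-12)

    def test_hand_value_clipped(self, rng):
        bounds3 = Bounds.cube(-3.0, 3.0, 1)
        pos = col(0.0, 2.0, 5.0, 3.0)
        pos = np.clip(pos, -3, 3)
        # same arithmetic as above but with X_e=3 (clipped data): 1+2+0.5*(3-3)=3
        prop = step_a2(pos, np.array([1.0]), 0, bounds3, rng,
                       peers=(1, 2, 3), r2=np.array([0.5]))
        assert prop[0] == pytest.approx(3.0, abs=1e-12)

    def test_equal_peers_zero_difference(self, bounds10, rng):
        pos = col(0.0, 2.0, 4.0, 4.0)
        for r2 in (0.0, 0.7, 1.0):
            prop = step_a2(pos, np.array([1.0]), 0, bounds10, rng,
                           peers=(1, 2, 3), r2=np.array([r2]))
            assert prop[0] == pytest.approx(3.0, abs=1e-12)


class TestStepB1:
    def test_full_attraction(self, bounds10, rng):
        pos = col(2.0, 0.0, 0.0, 0.0)
        prop = step_b1(pos, np.array([6.0]), 0, bounds10, rng,
                       r3=np.array([1.0]), r4=np.array([1.0]))
        assert prop[0] == pytest.approx(6.0, abs=1e-12)

    def test_identity(self, bounds10, rng):
        pos = col(2.0, 0.0, 0.0, 0.0)
        prop = step_b1(pos, np.array([6.0]), 0, bounds10, rng,
                       r3=np.array([1.0]), r4=np.array([0.0]))
        assert prop[0] == pytest.approx(2.0, abs=1e-12)

    def test_hand_value(self, bounds10, rng):
        # r3=0.5, r4=0.25: 0.5*2 + 0.25*(6-2) = 2
        pos = col(2.0, 0.0, 0.0, 0.0)
        prop = step_b1(pos, np.array([6.0]), 0, bounds10, rng,
                       r3=np.array([0.5]), r4=np.array([0.25]))
        assert prop[0] == pytest.approx(2.0, abs=1e-12)


class TestStepB2:
    def test_fixed_point(self, bounds10, rng):
        pos = col(1.0, 1.0, 0.0, 0.0)
        vals = np.array([2.0, 2.0, 9.0, 9.0])
        prop = step_b2(pos, vals, np.array([1.0]), 0, bounds10, rng,
                       partner=1, r_pair=(np.array([0.3]), np.array([0.8])))
        assert prop[0] == pytest.approx(1.0, abs=1e-12)

    def test_partner_better_branch(self, bounds10, rng):
        # X_i=4, X_r=2 better, best=0, r5=r6=0.5 -> 2 - 1 - 1 = 0
        pos = col(4.0, 2.0, 0.0, 0.0)
        vals = np.array([5.0, 1.0, 9.0, 9.0])
        prop = step_b2(pos, vals, np.array([0.0]), 0, bounds10, rng,
                       partner=1, r_pair=(np.array([0.5]), np.array([0.5])))
        assert prop[0] == pytest.approx(0.0, abs=1e-12)

    def test_self_better_branch(self, bounds10, rng):
        # X_i=2 better, X_r=4, best=0, r7=r8=0.5 -> 2 - 1 - 1 = 0
        pos = col(2.0, 4.0, 0.0, 0.0)
        vals = np.array([1.0, 5.0, 9.0, 9.0])
        prop = step_b2(pos, vals, np.array([0.0]), 0, bounds10, rng,
                       partner=1, r_pair=(np.array([0.5]), np.array([0.5])))
        assert prop[0] == pytest.approx(0.0, abs=1e-12)


def _sphere(x):
    return float(np.sum(x * x))


class TestPhases:
    def _setup(self, NP=6, D=2, seed=5, limit=10_000):
        rng = np.random.default_rng(seed)
        bounds = Bounds.cube(-5.0, 5.0, D)
        pos = rng.uniform(bounds.lb, bounds.ub, size=(NP, D))
        vals = np.array([_sphere(p) for p in pos])
        tracker = BestTracker()
        for p, v in zip(pos, vals):
            tracker.offer(p, v)
        return rng, bounds, pos, vals, tracker, Budget(limit)

    def test_investigation_never_worsens_members(self):
        rng, bounds, pos, vals, tracker, budget = self._setup()
        before = vals.copy()
        cfg = OptimizerConfig(NP=6, GEN=100)
        investigation_phase(pos, vals, tracker, bounds, _sphere, budget, rng, cfg)
        assert np.all(vals <= before)
        assert tracker.best_value <= before.min()

    def test_pursuit_never_worsens_members(self):
        rng, bounds, pos, vals, tracker, budget = self._setup()
        before = vals.copy()
        cfg = OptimizerConfig(NP=6, GEN=100)
        pursuit_phase(pos, vals, tracker, bounds, _sphere, budget, rng, cfg)
        assert np.all(vals <= before)

    def test_members_stay_in_bounds(self):
        rng, bounds, pos, vals, tracker, budget = self._setup(NP=8, D=3)
        cfg = OptimizerConfig(NP=8, GEN=10_000)
        for _ in range(5):
            investigation_phase(pos, vals, tracker, bounds, _sphere, budget, rng, cfg)
            pursuit_phase(pos, vals, tracker, bounds, _sphere, budget, rng, cfg)
        assert np.all(pos >= bounds.lb) and np.all(pos <= bounds.ub)

    def test_multiplier_range_property(self, bounds10, rng):
        # (r1 - 0.5)*2 spans [-1, 1]: proposals from the midpoint step stay
        # within the segment swept by that multiplier
        pos = col(4.0, 1.0, 3.0, 0.0)
        for _ in range(500):
            prop = step_a1(pos, 0, bounds10, rng, peers=(1, 2))
            # displacement = m * (4 - 2) with m in [-1, 1] -> prop in [2, 6]
            assert 2.0 - 1e-12 <= prop[0] <= 6.0 + 1e-12

    def test_stationary_when_draws_forced_zero(self, bounds10, rng):
        # regression guard: r1=0.5 (A1) and r3=1, r4=0 (B1) leave members put
        pos = col(1.0, -2.0, 3.0, 0.5)
        for i in range(4):
            a1 = step_a1(pos, i, bounds10, rng, peers=((i + 1) % 4, (i + 2) % 4),
                         r1=np.array([0.5]))
            b1 = step_b1(pos, np.array([9.0]), i, bounds10, rng,
                         r3=np.array([1.0]), r4=np.array([0.0]))
            assert a1[0] == pytest.approx(pos[i, 0], abs=1e-12)
            assert b1[0] == pytest.approx(pos[i, 0], abs=1e-12)
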