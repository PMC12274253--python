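"""State transition: pre-competition updates and the competition operator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protocells as pc
from protocells.dynamics import DEMAND, OLD, YOUNG

from oracles import case1_sequential


def _prestate(qtilde=None, pools=(0.0, 0.0, 0.0)):
    qtilde = np.zeros((3, 2)) if qtilde is None else np.asarray(qtilde, dtype=float)
    return pc.PreState(qtilde=qtilde, pools=np.asarray(pools, dtype=float))


# ---------------------------------------------------------------------------
# resolve_competition
# ---------------------------------------------------------------------------

def test_no_protocells_leave_all_nutrients_free():
    pre = _prestate(pools=(3.0, 1.0, 4.0))
    post = pc.resolve_competition(pre, active={0, 1, 2})
    assert post.qt.sum() == 0
    np.testing.assert_array_equal(post.free, pre.pools)
    np.testing.assert_array_equal(post.hidden, 0.0)


def test_generalist_only_hand_example():
    # hand evaluation of the published sequential formulas:
    # f_x = 3/4, f_x1 = 1/2, f_x2 = 1
    pre = _prestate(qtilde=[[2, 2], [0, 0], [0, 0]], pools=(3, 1, 4))
    post = pc.resolve_competition(pre, active={0})
    assert post.qt[0, YOUNG] == pytest.approx(1.5)
    assert post.qt[0, OLD] == pytest.approx(0.75)
    np.testing.assert_allclose(post.free, [0, 0, 2])
    np.testing.assert_allclose(post.hidden, [0.75, 0.25, 1.25])


def test_generalist_equilibrium_share():
    # the scarce-x split of the generalist-only regime: f_x = 20000/32361
    pre = _prestate(qtilde=[[20000, 12361], [0, 0], [0, 0]], pools=(20000, 50000, 50000))
    post = pc.resolve_competition(pre, active={0})
    f = 20000 / 32361
    assert post.qt[0, YOUNG] == pytest.approx(20000 * f)
    assert post.qt[0, OLD] == pytest.approx(12361 * f)


def test_inactive_species_pass_through_unchanged():
    pre = _prestate(qtilde=[[5, 5], [7, 3], [2, 1]], pools=(4, 0, 0))
    post = pc.resolve_competition(pre, active={0})
    np.testing.assert_array_equal(post.qt[1], pre.qtilde[1])
    np.testing.assert_array_equal(post.qt[2], pre.qtilde[2])


def test_parental_nutrient_return_flag():
    # scarce x kills half of 10 young T1; each failed one absorbed a unit of
    # x2 environmentally (always hidden) and carried a parental x1 unit
    # (hidden only under the strict-conservation flag)
    pre = _prestate(qtilde=[[0, 0], [10, 0], [0, 0]], pools=(5, 0, 100))
    default = pc.resolve_competition(pre, active={1})
    strict = pc.resolve_competition(pre, active={1}, return_parental_nutrients=True)
    np.testing.assert_allclose(default.hidden, [0, 0, 5])
    np.testing.assert_allclose(strict.hidden, [0, 5, 5])
    np.testing.assert_array_equal(strict.qt, default.qt)


def _random_case1_inputs(rng, n):
    scale = 10.0 ** rng.uniform(-2, 5, size=(n, 5))
    vals = scale * rng.uniform(0, 1, size=(n, 5))
    vals[rng.uniform(size=(n, 5)) < 0.08] = 0.0
    return vals


def test_product_form_matches_sequential_case1_formulas():
    """The product-of-fractions operator reproduces the published
    generalist-only (Case I) sequential min/max formulas."""
    rng = np.random.default_rng(1234)
    for qt01, qt02, qx, qx1, qx2 in _random_case1_inputs(rng, 2000):
        pre = _prestate(qtilde=[[qt01, qt02], [0, 0], [0, 0]], pools=(qx, qx1, qx2))
        post = pc.resolve_competition(pre, active={0})
        QT01, QT02, free, hidden = case1_sequential(qt01, qt02, qx, qx1, qx2)
        scale = max(1.0, qt01, qt02, qx, qx1, qx2)
        assert post.qt[0, YOUNG] == pytest.approx(QT01, rel=1e-12, abs=1e-12 * scale)
        assert post.qt[0, OLD] == pytest.approx(QT02, rel=1e-12, abs=1e-12 * scale)
        np.testing.assert_allclose(post.free, free, rtol=1e-12, atol=1e-12 * scale)
        np.testing.assert_allclose(post.hidden, hidden, rtol=1e-12, atol=1e-12 * scale)


@st.composite
def _prestates(draw):
    qtilde = np.array(
        [[draw(st.floats(0, 1e4)) for _ in range(2)] for _ in range(3)]
    )
    pools = np.array([draw(st.floats(0, 1e4)) for _ in range(3)])
    active = draw(st.sets(st.sampled_from([0, 1, 2]), min_size=1))
    return _prestate(qtilde, pools), active


@settings(derandomize=True, max_examples=150, deadline=None)
@given(_prestates())
def test_competition_conservation_and_bounds(case):
    """Per-nutrient conservation Q = free + consumed + hidden, and
    0 <= survivors <= pre-competition density."""
    pre, active = case
    post = pc.resolve_competition(pre, active)
    assert np.all(post.qt >= 0)
    assert np.all(post.qt <= pre.qtilde + 1e-9 * (1 + pre.qtilde))
    mask = np.zeros((3, 1), dtype=bool)
    for s in active:
        mask[s, 0] = True
    consumed = ((post.qt * mask)[:, :, None] * DEMAND).sum(axis=(0, 1))
    np.testing.assert_allclose(
        post.free + consumed + post.hidden,
        pre.pools,
        rtol=1e-9,
        atol=1e-9 * (1 + pre.pools.max()),
    )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(_prestates(), st.integers(0, 2), st.floats(1.0, 1e4))
def test_survivors_monotone_in_each_pool(case, nutrient, bump):
    pre, active = case
    lo = pc.resolve_competition(pre, active)
    pools = pre.pools.copy()
    pools[nutrient] += bump
    hi = pc.resolve_competition(_prestate(pre.qtilde, pools), active)
    assert np.all(hi.qt >= lo.qt - 1e-9 * (1 + lo.qt))


def test_abundance_means_everyone_survives_and_nothing_hides():
    pre = _prestate(qtilde=[[3, 4], [5, 6], [7, 8]], pools=(1e6, 1e6, 1e6))
    post = pc.resolve_competition(pre, active={0, 1, 2})
    np.testing.assert_array_equal(post.qt, pre.qtilde)
    np.testing.assert_array_equal(post.hidden, 0.0)


def test_empty_pool_kills_every_demander():
    pre = _prestate(qtilde=[[3, 4], [5, 6], [7, 8]], pools=(0.0, 1e6, 1e6))
    post = pc.resolve_competition(pre, active={0, 1, 2})
    np.testing.assert_array_equal(post.qt, 0.0)  # every class demands x


# ---------------------------------------------------------------------------
# pre_competition
# ---------------------------------------------------------------------------

def _simple_setup(b=-10.0, b1=0.0, b2=0.0, qx=0.0):
    sched = pc.ScheduleParams(tau0=1, tau1=1, tau2=1, horizon=3)
    grid = pc.build_grid(sched)
    params = pc.ModelParams(b=b, b1=b1, b2=b2)
    inits = pc.InitialDensities(qt=np.zeros((3, 2)), pools=(qx, 0.0, 0.0))
    return grid, params, inits


def test_initial_point_uses_initial_densities_verbatim():
    grid = pc.build_grid(pc.ScheduleParams(tau0=1, tau1=1, tau2=1, horizon=2))
    inits = pc.InitialDensities(qt=[[1, 2], [3, 4], [5, 6]], pools=(7, 8, 9))
    pre = pc.pre_competition([], grid, 0, pc.ModelParams(0, 0, 0), inits)
    np.testing.assert_array_equal(pre.qtilde, inits.qt)
    np.testing.assert_array_equal(pre.pools, inits.pools)


def test_negative_pool_is_clamped_to_zero():
    grid, params, inits = _simple_setup(b=-10.0, qx=0.0)
    _, post0 = pc.step([], grid, 0, params, inits)
    pre1 = pc.pre_competition([post0], grid, 1, params, inits)
    assert pre1.pools[0] == 0.0


def test_survivor_release_credited_at_next_operation_time():
    # one surviving generalist unit must add one unit of x1 and x2 at its
    # next operation time, nothing at intermediate points of other species
    sched = pc.ScheduleParams(tau0=1, tau1=0.5, tau2=0.5, horizon=1)
    grid = pc.build_grid(sched)
    params = pc.ModelParams(b=0, b1=0, b2=0)
    inits = pc.InitialDensities(qt=[[4, 0], [0, 0], [0, 0]], pools=(100, 100, 100))
    traj = pc.run(sched, params, inits)
    # t=0: the 4 young generalists consume only x (they carry parental
    # x1/x2) and all survive; t=0.5: specialists-only point, no release;
    # t=1: the generalist operates again and its 4 survivors release
    # 4 units of x1 and 4 of x2 into the environment.
    np.testing.assert_allclose(traj.pools_pre[1], [100 - 4, 100, 100])
    np.testing.assert_allclose(traj.pools_pre[2], [100 - 4, 104, 104])


def test_aging_survivors_total_becomes_young_and_young_become_old():
    sched = pc.ScheduleParams(tau0=1, tau1=1, tau2=1, horizon=1)
    grid = pc.build_grid(sched)
    params = pc.ModelParams(b=0, b1=0, b2=0)
    inits = pc.InitialDensities(qt=[[2, 3], [0, 0], [0, 0]], pools=(1e6, 1e6, 1e6))
    traj = pc.run(sched, params, inits)
    # abundant nutrients: all 5 survive at t=0 -> at t=1 young = 5, old = 2
    assert traj.pre[1].qtilde[0, YOUNG] == pytest.approx(5)
    assert traj.pre[1].qtilde[0, OLD] == pytest.approx(2)
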