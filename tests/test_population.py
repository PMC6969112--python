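"""Life-history calibration and the daily population step."""

import numpy as np
import pytest

import tgdrive as tg
from tgdrive.population import _SimContext, step_day
from tgdrive.genetics import wild_type_genotypes


def _det_run(lh, derived, cube, days, params=None):
    params = params or tg.CubeParams()
    state = tg.equilibrium_state(lh, derived, cube, mode="deterministic")
    ctx = _SimContext(cube, params, lh)
    for _ in range(days):
        state = step_day(
            state, cube, params, derived, lh, mode="deterministic", _ctx=ctx
        )
    return state


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_holds_equilibrium(default_life_history, default_derived, mendelian_full_gd):
    """With the printed life-history values, a deterministic no-release run
    keeps the adult population at N within 1% over a year."""
    state = _det_run(default_life_history, default_derived, mendelian_full_gd, 365)
    assert state.total_adults == pytest.approx(default_life_history.N, rel=0.01)


def test_calibration_rates_are_sane(default_derived):
    assert 0.0 < default_derived.mu_J < 1.0
    assert default_derived.alpha > 0.0
    assert 0.0 < default_derived.f_star < 1.0


def test_alpha_scales_linearly_with_n():
    d1 = tg.calibrate_life_history(tg.LifeHistoryParams(N=10_000))
    d2 = tg.calibrate_life_history(tg.LifeHistoryParams(N=20_000))
    assert d2.alpha == pytest.approx(2 * d1.alpha, rel=1e-9)
    assert d2.eq_larvae.sum() == pytest.approx(2 * d1.eq_larvae.sum(), rel=1e-9)
    assert d2.mu_J == pytest.approx(d1.mu_J, abs=1e-12)


def test_non_growing_population_rejected():
    with pytest.raises(ValueError, match="growth rate"):
        tg.LifeHistoryParams(r=0.99)


def test_infeasible_growth_rate_rejected():
    # r so large that even mu_J = 0 cannot sustain it
    with pytest.raises(ValueError, match="consistent"):
        tg.calibrate_life_history(tg.LifeHistoryParams(r=1.9))


# ---------------------------------------------------------------------------
# equilibrium state
# ---------------------------------------------------------------------------

def test_equilibrium_state_totals(default_life_history, default_derived, mendelian_full_gd):
    st = tg.equilibrium_state(
        default_life_history, default_derived, mendelian_full_gd, mode="stochastic"
    )
    n_geno = mendelian_full_gd.n_f + mendelian_full_gd.n_m
    assert abs(st.total_adults - default_life_history.N) <= n_geno
    assert st.eggs.dtype == np.int64 and st.eggs.min() >= 0


def test_equilibrium_state_is_wild_type_only(default_life_history, default_derived, mendelian_full_gd):
    cube = mendelian_full_gd
    st = tg.equilibrium_state(default_life_history, default_derived, cube)
    fwt, mwt = wild_type_genotypes(cube.architecture)
    assert st.adult_m[cube.male_index(mwt)] == st.total_adult_m
    assert st.adult_f[cube.female_index(fwt), cube.male_index(mwt)] == st.total_adult_f


def test_deterministic_fixed_point(default_life_history, default_derived, mendelian_full_gd):
    st0 = tg.equilibrium_state(
        default_life_history, default_derived, mendelian_full_gd, mode="deterministic"
    )
    st = _det_run(default_life_history, default_derived, mendelian_full_gd, 30)
    for a, b in (
        (st.eggs, st0.eggs), (st.larvae, st0.larvae), (st.pupae, st0.pupae),
        (st.adult_m, st0.adult_m), (st.adult_f, st0.adult_f),
    ):
        np.testing.assert_allclose(a, b, rtol=1e-9)


# ---------------------------------------------------------------------------
# step_day
# ---------------------------------------------------------------------------

def test_empty_state_stays_empty(default_life_history, default_derived, mendelian_full_gd, rng):
    lh = default_life_history
    cube = mendelian_full_gd
    st = tg.equilibrium_state(lh, default_derived, cube)
    for arr in (st.eggs, st.larvae, st.pupae, st.adult_m, st.adult_f, st.adult_f_unmated):
        arr[...] = 0
    nxt = step_day(st, cube, tg.CubeParams(), default_derived, lh, rng=rng)
    assert nxt.total_adults == 0
    assert nxt.eggs.sum() + nxt.larvae.sum() + nxt.pupae.sum() == 0


def test_stochastic_counts_stay_nonnegative_integers(rng):
    lh = tg.LifeHistoryParams(N=400)
    derived = tg.calibrate_life_history(lh)
    cube = tg.mendelian_cube("full_GD")
    st = tg.equilibrium_state(lh, derived, cube)
    ctx = _SimContext(cube, tg.CubeParams(), lh)
    for _ in range(300):
        st = step_day(st, cube, tg.CubeParams(), derived, lh, rng=rng, _ctx=ctx)
        for arr in (st.eggs, st.larvae, st.pupae, st.adult_m, st.adult_f):
            assert np.issubdtype(arr.dtype, np.integer)
            assert arr.min() >= 0


def test_no_males_leaves_females_unmated(default_life_history, default_derived, mendelian_full_gd, rng):
    lh = default_life_history
    cube = mendelian_full_gd
    st = tg.equilibrium_state(lh, default_derived, cube)
    st.adult_m[...] = 0
    st.adult_f[...] = 0
    st.pupae[:, cube.n_f :] = 0  # no sons about to emerge either
    nxt = step_day(st, cube, tg.CubeParams(), default_derived, lh, rng=rng)
    assert nxt.total_adult_m == 0
    assert nxt.adult_f.sum() == 0
    assert nxt.adult_f_unmated.sum() > 0  # emergers had no mates


def test_deterministic_matches_stochastic_expectation(rng):
    """One deterministic day equals the mean of many stochastic days from the
    same state (within Monte-Carlo error)."""
    lh = tg.LifeHistoryParams(N=300)
    derived = tg.calibrate_life_history(lh)
    cube = tg.mendelian_cube("full_GD")
    st_det = tg.equilibrium_state(lh, derived, cube, mode="deterministic")
    st_int = tg.equilibrium_state(lh, derived, cube, mode="stochastic")
    # align: run the deterministic step from the integerized state
    st0 = st_det.copy()
    st0.eggs = st_int.eggs.astype(float)
    st0.larvae = st_int.larvae.astype(float)
    st0.pupae = st_int.pupae.astype(float)
    st0.adult_m = st_int.adult_m.astype(float)
    st0.adult_f = st_int.adult_f.astype(float)
    st0.adult_f_unmated = st_int.adult_f_unmated.astype(float)
    params = tg.CubeParams()
    ctx = _SimContext(cube, params, lh)
    det = step_day(st0, cube, params, derived, lh, mode="deterministic", _ctx=ctx)

    n_draws = 3000
    tot_eggs = np.zeros(3)  # eggs, adults, larvae accumulators
    eggs0 = np.zeros_like(det.eggs[0])
    for _ in range(n_draws):
        s = step_day(st_int, cube, params, derived, lh, rng=rng, _ctx=ctx)
        tot_eggs += (s.eggs.sum(), s.total_adults, s.larvae.sum())
        eggs0 = eggs0 + s.eggs[0]
    mean_eggs, mean_adults, mean_larvae = tot_eggs / n_draws
    # newly laid cohort: Poisson(beta * females) split by the cube row
    assert mean_eggs == pytest.approx(det.eggs.sum(), rel=0.01)
    assert mean_adults == pytest.approx(det.total_adults, rel=0.01)
    assert mean_larvae == pytest.approx(det.larvae.sum(), rel=0.01)
    np.testing.assert_allclose(eggs0 / n_draws, det.eggs[0], rtol=0.05, atol=2.0)


# ---------------------------------------------------------------------------
# run_scenario
# ---------------------------------------------------------------------------

def _small_scenario(**kw):
    return tg.make_small_population_fixture(
        N=300, horizon=kw.pop("horizon", 120), **kw
    )


def test_same_master_seed_is_bit_identical():
    sc = _small_scenario(replicates=2, seed=42)
    t1 = tg.run_scenario(sc)
    t2 = tg.run_scenario(sc)
    np.testing.assert_array_equal(t1[0].adult_f, t2[0].adult_f)
    np.testing.assert_array_equal(t1[1].adult_m, t2[1].adult_m)
    # replicate streams differ from one another
    assert not np.array_equal(t1[0].adult_f, t1[1].adult_f)


def test_different_seeds_differ():
    t1 = tg.run_scenario(_small_scenario(seed=1))[0]
    t2 = tg.run_scenario(_small_scenario(seed=2))[0]
    assert not np.array_equal(t1.adult_f, t2.adult_f)


def test_ensemble_mean_tracks_equilibrium():
    """No releases: the stochastic ensemble mean adult count stays within
    2 standard errors of the calibrated N."""
    sc = _small_scenario(replicates=20, seed=3, releases=tg.ReleaseSchedule([]))
    trajs = tg.run_scenario(sc)
    finals = np.array([t.total_adults[-1] for t in trajs])
    se = finals.std(ddof=1) / np.sqrt(len(finals))
    assert abs(finals.mean() - 300) <= 2 * se + 1e-9


def test_mendelian_allele_frequency_has_no_drift():
    """Genotype-blind dynamics: with a Mendelian cube and no fitness costs,
    the transgene frequency performs an unbiased random walk."""
    sc = tg.Scenario(
        architecture="full_GD",
        cube_params=tg.CubeParams(q=0.0, d=0.0),
        life_history=tg.LifeHistoryParams(N=400),
        releases=tg.weekly_male_releases("full_GD", first_day=10, count=40),
        replicates=30,
        seed=9,
        horizon=150,
        burn_in=10,
    )
    trajs = tg.run_scenario(sc)
    from tgdrive.scenarios import allele_counts

    mids, finals = [], []
    for t in trajs:
        ac = allele_counts(t)
        freq = ac["T@A"] / ac[["W@A", "T@A", "R@A", "B@A"]].sum(axis=1)
        mids.append(freq.iloc[80])
        finals.append(freq.iloc[-1])
    drift = np.array(finals) - np.array(mids)
    se = drift.std(ddof=1) / np.sqrt(len(drift))
    assert abs(drift.mean()) <= 3 * se + 1e-12


def test_trajectory_tidy_export():
    sc = _small_scenario(horizon=30, seed=5)
    traj = tg.run_scenario(sc)[0]
    df = traj.to_dataframe(replicate=0)
    assert set(df.columns) == {"replicate", "day", "stage", "sex", "genotype", "count"}
    assert (df["count"] >= 0).all()
    assert df["day"].max() == sc.burn_in + 30
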