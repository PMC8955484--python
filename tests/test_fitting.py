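"""Fitting machinery: SSE, grid screen and greedy Monte Carlo (fast stand-in model)."""

import numpy as np
import pandas as pd
import pytest

from uniportsim import (
    ConfigError,
    FitConfig,
    NumericalError,
    ReleaseDataset,
    fit_release_data,
    grid_screen,
    mc_fit,
    sse,
)

TRUTH = {"D": 1.5e-13, "Dc": 1.5e-13}
BOUNDS = {"D": (1e-15, 1e-11), "Dc": (1e-15, 1e-11)}


def observed(fake_simulator, dose=1.0, params=TRUTH):
    c = fake_simulator(params, dose)
    mask = c.times > 0
    return c.times[mask], c.release[mask]


# ----------------------------------------------------------------- SSE
def test_sse_zero_for_identical_data(fake_simulator):
    t, r = observed(fake_simulator)
    assert sse(fake_simulator(TRUTH, 1.0), t, r) == 0.0


def test_sse_single_point_arithmetic(fake_simulator):
    c = fake_simulator(TRUTH, 1.0)
    t = np.array([150.0])
    r = np.interp(t, c.times, c.release) + 0.02
    assert sse(c, t, r) == pytest.approx(4e-4)


def test_sse_order_invariant_and_range_checked(fake_simulator):
    c = fake_simulator(TRUTH, 1.0)
    t, r = observed(fake_simulator)
    perm = np.random.default_rng(0).permutation(len(t))
    assert sse(c, t[perm], r[perm]) == pytest.approx(sse(c, t, r))
    with pytest.raises(ConfigError):
        sse(c, np.array([400.0]), np.array([0.5]))


# ----------------------------------------------------------- grid screen
def test_single_cell_grid_returns_that_cell(fake_simulator):
    t, r = observed(fake_simulator)
    params, _, n = grid_screen(t, r, 1.0, fake_simulator, BOUNDS, {"D": 1, "Dc": 1})
    assert n == 1
    assert set(params) == {"D", "Dc"}


def test_grid_runs_product_of_counts(fake_simulator):
    t, r = observed(fake_simulator)
    fake_simulator.calls = 0
    _, _, n = grid_screen(t, r, 1.0, fake_simulator, BOUNDS, {"D": 5, "Dc": 5})
    assert n == 25
    assert fake_simulator.calls == 25


def test_noiseless_data_at_grid_vertex_selects_that_vertex(fake_simulator):
    axes = np.geomspace(1e-15, 1e-11, 5)
    vertex = {"D": float(axes[3]), "Dc": float(axes[2])}
    t, r = observed(fake_simulator, params=vertex)
    params, best, _ = grid_screen(t, r, 1.0, fake_simulator, BOUNDS, {"D": 5, "Dc": 5})
    assert params == pytest.approx(vertex)
    assert best == 0.0


# ------------------------------------------------------------- Monte Carlo
def test_same_seed_gives_identical_fit(fake_simulator):
    t, r = observed(fake_simulator)
    start = {"D": 5e-14, "Dc": 5e-14}
    cfg = FitConfig(seed=123, max_iter=200, patience=50, bounds=BOUNDS)
    a = mc_fit(t, r, 1.0, fake_simulator, start, cfg)
    b = mc_fit(t, r, 1.0, fake_simulator, start, cfg)
    assert a.params == b.params
    assert np.array_equal(a.sse_trace, b.sse_trace)
    assert a.seed == 123


def test_accepted_moves_strictly_decrease_sse(fake_simulator):
    t, r = observed(fake_simulator)
    res = mc_fit(t, r, 1.0, fake_simulator, {"D": 5e-14, "Dc": 5e-14},
                 FitConfig(seed=1, max_iter=300, patience=100, bounds=BOUNDS))
    assert np.all(np.diff(res.sse_trace) < 0)
    assert res.sse == res.sse_trace[-1] <= res.sse_trace[0]
    assert res.accepted == len(res.sse_trace) - 1


def test_bounds_are_enforced(fake_simulator):
    t, r = observed(fake_simulator)
    tight = {"D": (4e-14, 6e-14), "Dc": (4e-14, 6e-14)}
    res = mc_fit(t, r, 1.0, fake_simulator, {"D": 5e-14, "Dc": 5e-14},
                 FitConfig(seed=5, max_iter=200, patience=40, bounds=tight))
    for k, (lo, hi) in tight.items():
        assert lo <= res.params[k] <= hi


def test_patience_stops_a_stuck_fit(fake_simulator):
    t, r = observed(fake_simulator)
    res = mc_fit(t, r, 1.0, fake_simulator, TRUTH,  # already optimal: nothing improves
                 FitConfig(seed=2, max_iter=10_000, patience=25, bounds=BOUNDS))
    assert res.n_iter == 25
    assert res.accepted == 0


def test_failed_simulations_are_rejected_not_fatal(fake_simulator):
    def flaky(params, dose):
        if params["D"] > 6e-14:
            raise NumericalError("synthetic failure region")
        return fake_simulator(params, dose)

    t, r = observed(fake_simulator)
    res = mc_fit(t, r, 1.0, flaky, {"D": 5.5e-14, "Dc": 5e-14},
                 FitConfig(seed=3, max_iter=150, patience=50, bounds=BOUNDS))
    assert res.params["D"] <= 6e-14


def test_parameter_recovery_on_the_stand_in_model(fake_simulator):
    t, r = observed(fake_simulator)
    start, _, _ = grid_screen(t, r, 1.0, fake_simulator, BOUNDS, {"D": 4, "Dc": 4})
    res = mc_fit(t, r, 1.0, fake_simulator, start,
                 FitConfig(seed=9, max_iter=600, patience=200, bounds=BOUNDS))
    assert res.params["D"] == pytest.approx(TRUTH["D"], rel=0.2)
    assert res.sse < 1e-6


# -------------------------------------------------- per-dose independence
def _dataset(fake_simulator, doses):
    rows = []
    for dose in doses:
        t, r = observed(fake_simulator, dose=dose)
        rows.extend((dose, float(tt), float(rr)) for tt, rr in zip(t, r))
    return ReleaseDataset(frame=pd.DataFrame(rows, columns=["dose_molpct", "time_s", "release"]))


def test_dataset_order_does_not_change_per_dose_results(ref, fake_simulator):
    ds = _dataset(fake_simulator, [0.5, 2.0])
    shuffled = ReleaseDataset(frame=ds.frame.sample(frac=1.0, random_state=4).reset_index(drop=True))
    cfg = FitConfig(seed=77, max_iter=40, patience=20, bounds=BOUNDS)
    kwargs = dict(
        carrier=ref.carrier, membrane=ref.membrane, dispersion=ref.dispersion,
        guest_in=ref.guest_in, sim_cfg=ref.sim, fit_cfg=cfg,
        grid_bounds=BOUNDS, grid_counts={"D": 2, "Dc": 2}, simulator=fake_simulator,
    )
    a = fit_release_data(ds, **kwargs)
    b = fit_release_data(shuffled, **kwargs)
    assert sorted(a) == sorted(b)
    for dose in a:
        assert a[dose].params == b[dose].params
        assert a[dose].seed == b[dose].seed


def test_dataset_validation():
    with pytest.raises(ConfigError):
        ReleaseDataset(frame=pd.DataFrame({"dose_molpct": [1.0], "time_s": [-1.0], "release": [0.5]}))
    with pytest.raises(ConfigError):
        ReleaseDataset(frame=pd.DataFrame({"dose_molpct": [1.0], "time_s": [5.0], "release": [1.2]}))
    with pytest.raises(ConfigError):
        ReleaseDataset(frame=pd.DataFrame({"time_s": [5.0], "release": [0.2]}))
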