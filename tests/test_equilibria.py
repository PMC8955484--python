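"""Equilibrium solver: examples, residual certificates, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uniportsim import (
    CarrierSpec,
    CompartmentTotals,
    ConfigError,
    complex_partition,
    equilibrium_residuals,
    kf_water,
    partition_factor,
    solve_equilibrium,
)

GAMMA_L = 0.762
REF_CARRIER = dict(P=676.0, Kfm=1480.0, Kfs=8.34e-9, D=1.5e-13, Dc=1.5e-13)


def totals(Htot=3.7e-6, Gtot=0.0, volume=1.0, L=3.7e-4):
    return CompartmentTotals(Htot=Htot, Gtot=Gtot, volume=volume, L_global=L)


# ---------------------------------------------------------------- kf_water
@pytest.mark.parametrize(
    "w_pct,expected,rel",
    [
        (0.0, 1480.0, 1e-12),     # exp(0) = 1
        (10.0, 1.1e2, 5e-2),      # two significant figures
        (100.0, 7.56e-9, 1e-2),   # direct evaluation of the fit
    ],
)
def test_kf_water_examples(w_pct, expected, rel):
    assert kf_water(w_pct, 1480.0, 0.26) == pytest.approx(expected, rel=rel)


@pytest.mark.parametrize("bad", [dict(w_pct=-1), dict(w_pct=101), dict(a=0.0), dict(a=-5.0)])
def test_kf_water_preconditions(bad):
    kwargs = dict(w_pct=10.0, a=1480.0, b=0.26)
    kwargs.update(bad)
    with pytest.raises(ConfigError):
        kf_water(**kwargs)


# --------------------------------------------------------- partition terms
def test_partition_factor_reference_value():
    assert partition_factor(676.0, 0.762, 3.7e-4) == pytest.approx(0.1906, rel=1e-3)
    assert partition_factor(0.0, 0.762, 3.7e-4) == 0.0


@given(
    P=st.floats(1.0, 1e5),
    gammaL=st.floats(0.1, 2.0),
    L=st.floats(1e-6, 1e-2),
    bump=st.floats(1.01, 10.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_partition_factor_increasing_in_each_argument(P, gammaL, L, bump):
    base = partition_factor(P, gammaL, L)
    assert partition_factor(P * bump, gammaL, L) > base
    assert partition_factor(P, gammaL * bump, L) > base
    assert partition_factor(P, gammaL, L * bump) > base


def test_complex_partition_values():
    # Kfm == Kfs collapses K'p to the carrier partition constant P*gammaL/gammaW
    assert complex_partition(676.0, 0.762, 0.018, 5.0, 5.0) == pytest.approx(2.86e4, rel=1e-2)
    assert complex_partition(676.0, 0.762, 0.018, 1480.0, 8.34e-9) == pytest.approx(5.08e15, rel=1e-2)
    assert math.isnan(complex_partition(676.0, 0.762, 0.018, 1480.0, 0.0))


# ------------------------------------------------------- solve_equilibrium
def test_no_carrier_means_no_carrier_species():
    s = solve_equilibrium(totals(Htot=0.0, Gtot=0.489), CarrierSpec(**REF_CARRIER), GAMMA_L)
    assert (s.Hs, s.HGs, s.Hm, s.HGm, s.Hz) == (0, 0, 0, 0, 0)
    assert s.G == 0.489


def test_guest_free_case_is_a_linear_partition_split():
    # with Gtot = 0 the quadratic degenerates: Hs = Htot/(1+pf), Hm = pf*Hs
    s = solve_equilibrium(totals(Htot=3.7e-6, Gtot=0.0), CarrierSpec(**REF_CARRIER), GAMMA_L)
    assert s.Hs == pytest.approx(3.108e-6, rel=1e-3)
    assert s.Hm == pytest.approx(5.92e-7, rel=1e-3)
    assert s.HGs == s.HGm == 0.0


def _random_cases(n, seed, with_aggregation):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        carrier = CarrierSpec(
            P=10 ** rng.uniform(-1, 5),
            Kfm=10 ** rng.uniform(-2, 6),
            Kfs=10 ** rng.uniform(-9, 2),
            D=1e-13,
            Dc=1e-13,
            Kag=10 ** rng.uniform(15, 23) if with_aggregation else 0.0,
            z=rng.uniform(2.0, 8.0),
        )
        t = totals(
            Htot=10 ** rng.uniform(-8, -4),
            Gtot=10 ** rng.uniform(-4, 0) if rng.random() < 0.8 else 0.0,
            L=10 ** rng.uniform(-5, -2),
        )
        yield carrier, t


@pytest.mark.parametrize("with_aggregation", [False, True])
def test_residual_certificate_on_random_draws(with_aggregation):
    """Returned states satisfy every defining equation and both balances."""
    for carrier, t in _random_cases(200, seed=42, with_aggregation=with_aggregation):
        s = solve_equilibrium(t, carrier, GAMMA_L)
        res = equilibrium_residuals(s, t, carrier, GAMMA_L)
        assert max(res.values()) < 1e-9, (carrier, t, res)


def test_analytic_and_newton_paths_agree_without_aggregation():
    for carrier, t in _random_cases(200, seed=7, with_aggregation=False):
        a = solve_equilibrium(t, carrier, GAMMA_L, method="analytic")
        n = solve_equilibrium(t, carrier, GAMMA_L, method="newton")
        assert n.Hs == pytest.approx(a.Hs, rel=1e-10)


def _bisect_oracle(carrier, t, gammaL, iters=200):
    """Independent dense-bisection root of the carrier mass balance."""
    pf = carrier.P * gammaL * t.L_global
    c = pf * carrier.Kfm + carrier.Kfs

    def balance(x):
        G = t.Gtot / (1.0 + c * x)
        agg = carrier.z * carrier.Kag * x**carrier.z if carrier.Kag > 0 else 0.0
        return x * (1 + pf) + (carrier.Kfs + pf * carrier.Kfm) * x * G + agg - t.Htot

    lo, hi = 0.0, t.Htot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if balance(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("with_aggregation", [False, True])
def test_root_matches_brute_force_bisection(with_aggregation):
    for carrier, t in _random_cases(50, seed=3, with_aggregation=with_aggregation):
        s = solve_equilibrium(t, carrier, GAMMA_L)
        assert s.Hs == pytest.approx(_bisect_oracle(carrier, t, GAMMA_L), rel=1e-9)


def test_membrane_bound_carrier_monotone_in_partition():
    hm = [
        solve_equilibrium(totals(Gtot=0.489), CarrierSpec(**{**REF_CARRIER, "P": P}), GAMMA_L).Hm
        for P in (10, 100, 676, 3000, 1e4)
    ]
    assert all(b >= a for a, b in zip(hm, hm[1:]))


def test_membrane_complex_monotone_in_binding_constant():
    hgm = [
        solve_equilibrium(totals(Gtot=0.489), CarrierSpec(**{**REF_CARRIER, "Kfm": K}), GAMMA_L).HGm
        for K in (1.0, 50, 1480, 1e4, 1e6)
    ]
    assert all(b >= a for a, b in zip(hgm, hgm[1:]))


def test_aggregated_amount_monotone_in_Kag_and_opposite_in_z():
    agg_vs_K = [
        5.0 * solve_equilibrium(totals(), CarrierSpec(**REF_CARRIER, Kag=K, z=5.0), GAMMA_L).Hz
        for K in (1e18, 1e20, 1e21, 1e22)
    ]
    assert all(b >= a for a, b in zip(agg_vs_K, agg_vs_K[1:]))
    agg_vs_z = [
        z * solve_equilibrium(totals(), CarrierSpec(**REF_CARRIER, Kag=1e21, z=z), GAMMA_L).Hz
        for z in (4.0, 5.0, 6.0, 7.0, 8.0)
    ]
    assert all(b <= a for a, b in zip(agg_vs_z, agg_vs_z[1:]))


def test_non_integer_aggregation_numbers_are_supported():
    for z in (4.8, 5.2):
        carrier = CarrierSpec(**REF_CARRIER, Kag=1e21, z=z)
        s = solve_equilibrium(totals(), carrier, GAMMA_L)
        assert s.Hz > 0
        assert max(equilibrium_residuals(s, totals(), carrier, GAMMA_L).values()) < 1e-9


def test_analytic_path_refuses_aggregation():
    with pytest.raises(ConfigError):
        solve_equilibrium(totals(), CarrierSpec(**REF_CARRIER, Kag=1e21, z=5.0), GAMMA_L, method="analytic")
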