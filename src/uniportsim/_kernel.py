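"""Numba-compiled numerical core.

Everything here works on plain floats in a fixed convention: concentrations
in mol L^-1 referenced to the compartment water volume, amounts in moles,
areas in m^2, the flux prefactors ``kD = D/w*1000`` and ``kC = Dc/w*1000``
in mol m^-2 s^-1 per (mol L^-1) of gradient.

The free-carrier concentration in solution, ``x = [H]_s``, is the single
unknown of the per-compartment equilibrium problem.  Substituting the
partition and binding relations into the carrier mass balance gives

    f(x) = z*Kag*c*x^(z+1) + z*Kag*x^z + A*x^2 + B*x - Htot = 0

with ``c = pf*Kfm + Kfs``, ``A = (1+pf)*c`` and
``B = 1 + pf + c*(Gtot - Htot)``, where ``pf = P*gammaL*[L]`` is the
partition factor.  Without aggregation (Kag = 0) the quadratic is solved in
closed form; otherwise a Newton iteration safeguarded by bisection on
(0, Htot] is used.  f(0+) = -Htot < 0 and f(Htot) >= 0, and f is strictly
increasing on the physical branch, so the bracket always contains the unique
physical root.
"""

import numpy as np
from numba import njit

# run_interval status codes -> offending donor pool
STATUS_MESSAGES = {
    1: "membrane-bound carrier, EV leaflet",
    2: "membrane-bound carrier, IV leaflet",
    3: "membrane-bound complex, EV leaflet",
    4: "membrane-bound complex, IV leaflet",
    5: "equilibrium solver failed to converge",
}

NEWTON_MAX_ITER = 200
NEWTON_REL_TOL = 1e-12


@njit(cache=True, inline='always')
def solve_hs_closed(Htot, Gtot, pf, Kfm, Kfs):
    """Positive root of the quadratic carrier balance (no aggregation)."""
    if Htot <= 0.0:
        return 0.0
    c = pf * Kfm + Kfs
    A = (1.0 + pf) * c
    B = 1.0 + pf + c * (Gtot - Htot)
    if A == 0.0:
        # no binding/partition sinks beyond the linear split; B = 1 + pf > 0
        return Htot / B
    if B >= 0.0:
        # stable form, avoids cancellation when 4*A*Htot << B^2
        return 2.0 * Htot / (B + np.sqrt(B * B + 4.0 * A * Htot))
    return (-B + np.sqrt(B * B + 4.0 * A * Htot)) / (2.0 * A)


@njit(cache=True)
def solve_hs_numeric(Htot, Gtot, pf, Kfm, Kfs, Kag, z, x0):
    """Safeguarded Newton root of the general carrier balance.

    Returns ``(x, status)`` with status 0 on success, 1 on non-convergence.
    ``x0`` is the initial guess; anything outside (0, Htot] falls back to
    Htot (the documented starting point).
    """
    if Htot <= 0.0:
        return 0.0, 0
    c = pf * Kfm + Kfs
    A = (1.0 + pf) * c
    B = 1.0 + pf + c * (Gtot - Htot)
    lo = 0.0
    hi = Htot
    x = x0
    if not (0.0 < x <= hi):
        x = hi
    for _ in range(NEWTON_MAX_ITER):
        if Kag > 0.0:
            xz = x**z
            f = z * Kag * xz * (c * x + 1.0) + A * x * x + B * x - Htot
            df = z * Kag * xz * ((z + 1.0) * c + z / x) + 2.0 * A * x + B
        else:
            f = A * x * x + B * x - Htot
            df = 2.0 * A * x + B
        if f > 0.0:
            hi = x
        elif f < 0.0:
            lo = x
        else:
            return x, 0
        if df > 0.0:
            x_new = x - f / df
        else:
            x_new = 0.5 * (lo + hi)
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) <= NEWTON_REL_TOL * x_new:
            return x_new, 0
        x = x_new
    # Newton did not meet the step tolerance; tighten by pure bisection.
    for _ in range(200):
        x = 0.5 * (lo + hi)
        if Kag > 0.0:
            xz = x**z
            f = z * Kag * xz * (c * x + 1.0) + A * x * x + B * x - Htot
        else:
            f = A * x * x + B * x - Htot
        if f > 0.0:
            hi = x
        else:
            lo = x
        if hi - lo <= NEWTON_REL_TOL * hi:
            return 0.5 * (lo + hi), 0
    return x, 1


@njit(cache=True, inline='always')
def solve_hs(Htot, Gtot, pf, Kfm, Kfs, Kag, z, x0):
    """Dispatch: closed form when aggregation is off, Newton otherwise."""
    if Kag == 0.0:
        return solve_hs_closed(Htot, Gtot, pf, Kfm, Kfs), 0
    return solve_hs_numeric(Htot, Gtot, pf, Kfm, Kfs, Kag, z, x0)


@njit(cache=True)
def run_interval(
    nH_o,
    nG_o,
    nH_i,
    nG_i,
    Vout,
    Vin,
    pf,
    Kfm,
    Kfs,
    Kag,
    z,
    kD,
    kC,
    A_out,
    A_in,
    ts,
    n_steps,
    rem,
    xo,
    xi,
):
    """Advance the two-compartment pools by ``n_steps`` steps of ``ts`` plus
    one remainder step of ``rem`` (skipped when 0).

    Each step: re-equilibrate both compartments, evaluate the Fick flux
    densities of the membrane-bound carrier and complex, move ``J*A*dt``
    moles from the donor to the acceptor side (the donor leaflet's area is
    used, so the transfer conserves mass exactly) and fold the transferred
    moles into the compartment totals.  ``xo``/``xi`` carry the previous
    roots as warm starts; the root is unique so this cannot change results.

    Returns ``(status, nH_o, nG_o, nH_i, nG_i, xo, xi, steps_done)``;
    nonzero status codes are listed in ``STATUS_MESSAGES`` and the pools are
    returned as they were before the offending step.
    """
    c = pf * Kfm + Kfs
    total = n_steps + (1 if rem > 0.0 else 0)
    for k in range(total):
        dt = ts if k < n_steps else rem
        Htot_o = nH_o / Vout
        Gtot_o = nG_o / Vout
        Htot_i = nH_i / Vin
        Gtot_i = nG_i / Vin
        xo, st = solve_hs(Htot_o, Gtot_o, pf, Kfm, Kfs, Kag, z, xo)
        if st != 0:
            return 5, nH_o, nG_o, nH_i, nG_i, xo, xi, k
        xi, st = solve_hs(Htot_i, Gtot_i, pf, Kfm, Kfs, Kag, z, xi)
        if st != 0:
            return 5, nH_o, nG_o, nH_i, nG_i, xo, xi, k

        G_o = Gtot_o / (1.0 + c * xo)
        G_i = Gtot_i / (1.0 + c * xi)
        Hm_o = pf * xo
        Hm_i = pf * xi
        HGm_o = Kfm * Hm_o * G_o
        HGm_i = Kfm * Hm_i * G_i

        gH = Hm_o - Hm_i
        dH = kD * gH * (A_out if gH > 0.0 else A_in) * dt
        gC = HGm_o - HGm_i
        dC = kC * gC * (A_out if gC > 0.0 else A_in) * dt

        if dH > Hm_o * Vout or -dH > Hm_i * Vin:
            return (1 if dH > 0.0 else 2), nH_o, nG_o, nH_i, nG_i, xo, xi, k
        if dC > HGm_o * Vout or -dC > HGm_i * Vin:
            return (3 if dC > 0.0 else 4), nH_o, nG_o, nH_i, nG_i, xo, xi, k

        nH_o -= dH + dC
        nH_i += dH + dC
        nG_o -= dC
        nG_i += dC
    return 0, nH_o, nG_o, nH_i, nG_i, xo, xi, total
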