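"""Independently coded arithmetic oracles for the model right-hand sides.

These deliberately avoid the package's own helper functions: every term is
written out as plain scalar arithmetic, summed brute-force, so that agreement
with the vectorized implementations is a genuine cross-check rather than a
tautology.
"""

import math


def oracle_phage_rhs(state, p, env):
    """Brute-force term-sum derivative of the phage model.

    ``state`` is (N, N_R, C, C_R, P, R); ``p`` and ``env`` are plain dicts of
    parameter values.  Returns a 6-list (dN, dN_R, dC, dC_R, dP, dR).
    """
    N, N_R, C, C_R, P, R = state
    k, w, A, e = env["k"], env["w"], env["A"], env["e"]
    refuge = env["refuge_density"]

    def psi(V):
        return V * R / (k + R)

    def excess(h):
        return h - refuge if h > refuge else 0.0

    # MOI-dependent effective killing rate on immune cells (Hill in M)
    M = P / (C_R if C_R > 1.0 else 1.0)
    if M == 0.0 or p["x"] == 0.0:
        d_CR = p["delta_MIN"]
    else:
        hill = M ** p["n"] / (p["q"] ** p["n"] + M ** p["n"])
        d_CR = p["delta_MIN"] + p["x"] * (p["delta_MAX"] - p["delta_MIN"]) * hill

    ads_N = p["delta_N"] * excess(N) * P
    ads_C = p["delta_C"] * excess(C) * P
    kill_CR = d_CR * excess(C_R) * P
    sink_CR = p["delta_MAX"] * excess(C_R) * P
    mut = p["mu"] * psi(p["V_N"]) * N

    dN = psi(p["V_N"]) * N - mut - ads_N - w * N
    dN_R = psi(p["V_NR"]) * N_R + mut - w * N_R
    dC = psi(p["V_C"]) * C - ads_C + p["v"] * C_R - w * C
    dC_R = (
        psi(p["V_CR"]) * C_R
        + p["m"] * ads_C
        - kill_CR
        - p["v"] * C_R
        - w * C_R
    )
    dP = (
        p["beta_N"] * ads_N
        + p["beta_C"] * (1.0 - p["m"]) * ads_C
        - p["m"] * ads_C
        + p["beta_CR"] * kill_CR
        - sink_CR
        - w * P
    )
    uptake = (
        psi(p["V_N"]) * N
        + psi(p["V_NR"]) * N_R
        + psi(p["V_C"]) * C
        + psi(p["V_CR"]) * C_R
    )
    dR = w * (A - R) - e * uptake
    return [dN, dN_R, dC, dC_R, dP, dR]


def oracle_plasmid_rhs(state, p, env):
    """Brute-force term-sum derivative of the plasmid model.

    ``state`` is (N, N_P, C, C_P, C_X, R).  Returns a 6-list.
    """
    N, N_P, C, C_P, C_X, R = state
    k, w, A, e = env["k"], env["w"], env["A"], env["e"]

    def psi(V):
        return V * R / (k + R)

    T_N = (p["gamma_NN"] * N_P + p["gamma_CN"] * C_P) * N
    T_C = (p["gamma_NC"] * N_P + p["gamma_CC"] * C_P) * C
    z_X = p["z"] * C_X if p.get("z_on_CX") else 0.0

    dN = psi(p["V_N"]) * N - T_N + p["tau_N"] * N_P + p["z"] * C + z_X - w * N
    dN_P = psi(p["V_NP"]) * N_P + T_N - p["tau_N"] * N_P + p["z"] * C_P - w * N_P
    dC = (
        psi(p["V_C"]) * C
        - T_C
        + p["tau_C"] * C_P
        + p["v"] * C_X
        - p["z"] * C
        - w * C
    )
    dC_P = (
        psi(p["V_CP"]) * C_P
        + (1.0 - p["m"]) * T_C
        - p["tau_C"] * C_P
        - p["z"] * C_P
        - w * C_P
    )
    dC_X = psi(p["V_X"]) * C_X + p["m"] * T_C - p["v"] * C_X - z_X - w * C_X
    uptake = (
        psi(p["V_N"]) * N
        + psi(p["V_NP"]) * N_P
        + psi(p["V_C"]) * C
        + psi(p["V_CP"]) * C_P
        + psi(p["V_X"]) * C_X
    )
    dR = w * (A - R) - e * uptake
    return [dN, dN_P, dC, dC_P, dC_X, dR]


def oracle_decline_quadrature(P0, C_R0, V_R, delta_MAX, t):
    """Direct quadrature of dP/dt = -delta_MAX * C_R0 * exp(V_R*s) * P.

    Solved with scipy's initial-value integrator on the log-density (the
    defining ODE, not the closed form), evaluated at time ``t``.
    """
    from scipy.integrate import solve_ivp

    def rhs(s, logP):
        return [-delta_MAX * C_R0 * math.exp(V_R * s)]

    sol = solve_ivp(
        rhs, (0.0, t), [math.log(P0)], rtol=1e-11, atol=1e-12,
        dense_output=True,
    )
    return math.exp(sol.sol(t)[0])
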