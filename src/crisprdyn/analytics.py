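"""Closed-form equilibria and invasion/maintenance criteria.

These are the analytic companions to the simulators: the resource and
bacterial densities at the phage- and plasmid-free chemostat equilibrium, the
threshold condition for a lytic phage to establish on a sensitive resident
population, the critical conjugative transfer rate for a deleterious plasmid
to be maintained, and the expected decline of free phage adsorbing to an
exponentially growing fully immune culture (a batch-culture test of the
maximum-adsorption assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ChemostatEnv

__all__ = [
    "WashoutError",
    "ThresholdReport",
    "resource_equilibrium",
    "bacterial_equilibrium",
    "phage_establishment_threshold",
    "critical_gamma",
    "immune_decline_curve",
    "phage_establishment_report",
    "plasmid_maintenance_report",
]


class WashoutError(ValueError):
    """The population cannot grow as fast as it is diluted (w ≥ V)."""


@dataclass(frozen=True)
class ThresholdReport:
    """An invasion/maintenance criterion evaluated for one parameter set."""

    criterion: str
    threshold: float
    units: str
    parameters: dict = field(default_factory=dict)
    satisfied: bool | None = None

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "threshold": self.threshold,
            "units": self.units,
            "parameters": self.parameters,
            "satisfied": self.satisfied,
        }


def resource_equilibrium(V: float, k: float, w: float) -> float:
    """Resource concentration R* = k·w/(V−w) at which growth balances washout.

    Raises :class:`WashoutError` when ``w ≥ V`` (no positive equilibrium: the
    population washes out).
    """
    if k <= 0:
        raise ValueError("Monod constant k must be positive")
    if w < 0:
        raise ValueError("dilution rate w must be nonnegative")
    if w >= V:
        raise WashoutError(
            f"dilution rate w={w} is not below the maximum growth rate V={V}"
        )
    return k * w / (V - w)


def bacterial_equilibrium(env: ChemostatEnv, V: float) -> float:
    """Equilibrium density N* = (A − R*)/e of a single phage-free population.

    At steady state the resource settles at R* and everything taken up above
    R* has been converted to cells at efficiency e.
    """
    R_star = resource_equilibrium(V, env.k, env.w)
    return (env.A - R_star) / env.e


def phage_establishment_threshold(w: float, N_star: float) -> float:
    """Critical value of δ_N·β_N above which a lytic phage establishes.

    A phage introduced into a chemostat with sensitive residents at density
    ``N_star`` spreads iff its production rate exceeds washout,
    ``δ_N·β_N·N* > w``; the returned critical product is ``w/N*`` (ml·hr⁻¹).
    """
    if N_star <= 0:
        raise ValueError("resident equilibrium density N_star must be positive")
    if w < 0:
        raise ValueError("dilution rate w must be nonnegative")
    return w / N_star


def critical_gamma(
    V_N: float, V_NP: float, w: float, tau_N: float, N_star: float
) -> float:
    """Critical conjugative transfer rate constant for plasmid maintenance.

    With the plasmid-free resident at equilibrium its realized growth rate
    equals w, so the plasmid-bearing strain grows at ``w·V_NP/V_N`` and runs a
    deficit ``w·(1 − V_NP/V_N)``; adding segregation losses, infectious
    transfer maintains the plasmid iff

        γ_NN · N* > w·(1 − V_NP/V_N) + τ_N.

    Returns the critical γ_NN (ml·cell⁻¹·hr⁻¹).
    """
    if V_N <= 0:
        raise ValueError("resident maximum growth rate V_N must be positive")
    if N_star <= 0:
        raise ValueError("resident equilibrium density N_star must be positive")
    return (w * (1.0 - V_NP / V_N) + tau_N) / N_star


def immune_decline_curve(
    P0: float, C_R0: float, V_R: float, delta_MAX: float, t
):
    """Free-phage density P(t) on an exponentially growing immune culture.

    In batch culture immune cells grow as ``C_R(t) = C_R0·e^{V_R·t}`` and
    adsorb phage at the maximum rate with no replication, so
    ``dP/dt = −δ_MAX·C_R(t)·P`` integrates to

        P(t) = P0·exp(−δ_MAX·C_R0·(e^{V_R·t} − 1)/V_R),

    with the ``V_R = 0`` limit ``P0·exp(−δ_MAX·C_R0·t)``.  ``t`` may be a
    scalar or array of hours.
    """
    if P0 < 0 or C_R0 < 0 or V_R < 0 or delta_MAX < 0:
        raise ValueError("all arguments must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if V_R == 0.0:
        exponent = delta_MAX * C_R0 * t
    else:
        exponent = delta_MAX * C_R0 * np.expm1(V_R * t) / V_R
    out = P0 * np.exp(-exponent)
    return float(out) if out.ndim == 0 else out


def phage_coexistence_equilibrium(
    env: ChemostatEnv, V: float, delta: float, beta: float
) -> tuple[float, float, float]:
    """Fixed point ``(N*, P*, R*)`` of the two-species bacteria–phage pair.

    Phage balance pins the host at ``N* = w/(β·δ)``; the resource settles
    where inflow matches uptake by that host density (the positive root of
    ``w(A−R)(k+R) = e·V·N*·R``); and host balance then gives
    ``P* = (ψ(R*) − w)/δ``.  Raises :class:`WashoutError` when the phage
    cannot be supported (``P* ≤ 0``).
    """
    if delta <= 0 or beta <= 0:
        raise ValueError("delta and beta must be positive")
    N_star = env.w / (beta * delta)
    # w(A-R)(k+R) - e V N* R = 0  ->  w R^2 + (wk + eVN* - wA) R - wAk = 0
    a = env.w
    b = env.w * env.k + env.e * V * N_star - env.w * env.A
    c = -env.w * env.A * env.k
    R_star = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    psi = V * R_star / (env.k + R_star)
    P_star = (psi - env.w) / delta
    if P_star <= 0:
        raise WashoutError(
            "phage cannot be maintained: host growth at R* does not exceed washout"
        )
    return N_star, P_star, R_star


def phage_establishment_report(
    env: ChemostatEnv, V_N: float, delta_N: float, beta_N: float
) -> ThresholdReport:
    """Evaluate the phage establishment criterion for one parameter set."""
    N_star = bacterial_equilibrium(env, V_N)
    threshold = phage_establishment_threshold(env.w, N_star)
    return ThresholdReport(
        criterion="phage_establishment",
        threshold=threshold,
        units="ml hr^-1 (critical delta_N*beta_N)",
        parameters={
            "w": env.w, "N_star": N_star, "V_N": V_N,
            "delta_N": delta_N, "beta_N": beta_N,
        },
        satisfied=delta_N * beta_N > threshold,
    )


def plasmid_maintenance_report(
    env: ChemostatEnv,
    V_N: float,
    V_NP: float,
    tau_N: float,
    gamma_NN: float,
) -> ThresholdReport:
    """Evaluate the plasmid maintenance criterion for one parameter set."""
    N_star = bacterial_equilibrium(env, V_N)
    threshold = critical_gamma(V_N, V_NP, env.w, tau_N, N_star)
    return ThresholdReport(
        criterion="plasmid_maintenance",
        threshold=threshold,
        units="ml cell^-1 hr^-1 (critical gamma_NN)",
        parameters={
            "w": env.w, "N_star": N_star, "V_N": V_N, "V_NP": V_NP,
            "tau_N": tau_N, "gamma_NN": gamma_NN,
        },
        satisfied=gamma_NN > threshold,
    )
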