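"""Conjugative-plasmid model: chemostat dynamics of CRISPR immunity against a
self-transmissible plasmid.

Five bacterial populations share the vessel with the resource R:

* ``N``   — plasmid-free non-CRISPR,
* ``N_P`` — plasmid-bearing non-CRISPR,
* ``C``   — plasmid-free CRISPR (no matching spacer),
* ``C_P`` — plasmid-bearing CRISPR,
* ``C_X`` — CRISPR cells immune to receipt of the plasmid.

Plasmids transfer by conjugation at rates proportional to donor×recipient
densities with rate constants ``gamma_NN`` (N_P→N), ``gamma_NC`` (N_P→C),
``gamma_CN`` (C_P→N) and ``gamma_CC`` (C_P→C), and are lost by vegetative
segregation at per-hour rates ``tau_N`` (N_P→N) and ``tau_C`` (C_P→C).  A
fraction ``m`` of transfers into C abort and immunize the recipient directly
(C→C_X); immunity is lost at rate ``v`` (C_X→C), and the CRISPR element itself
is lost at rate ``z`` (C→N, C_P→N_P).  C_X carries no complete plasmid and
donates nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import ChemostatEnv, StateVector, Trajectory, integrate, monod_growth

__all__ = [
    "PLASMID_ROSTER",
    "PlasmidParams",
    "PlasmidState",
    "plasmid_rhs",
    "simulate_plasmid",
]

#: Population labels in roster (column) order.
PLASMID_ROSTER: tuple[str, ...] = ("N", "N_P", "C", "C_P", "C_X")


@dataclass(frozen=True)
class PlasmidParams:
    """Complete parameter set of the plasmid model.

    Growth rates V are hr⁻¹, transfer rate constants gamma are ml per cell per
    hour, segregation rates tau and the conversion rates v and z are hr⁻¹, m
    is a probability.  ``z_on_CX`` optionally extends CRISPR-element loss to
    the immune C_X population (C_X→N); by default only C and C_P lose it.
    """

    V_N: float = 1.0
    V_NP: float = 0.95
    V_C: float = 0.97
    V_CP: float = 0.88
    V_X: float = 0.96
    gamma_NN: float = 1e-9
    gamma_NC: float = 1e-9
    gamma_CN: float = 1e-9
    gamma_CC: float = 1e-9
    tau_N: float = 1e-3
    tau_C: float = 1e-3
    m: float = 0.2
    v: float = 1e-3
    z: float = 1e-8
    z_on_CX: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("immunization probability m must lie in [0, 1]")
        for name in ("V_N", "V_NP", "V_C", "V_CP", "V_X", "gamma_NN",
                     "gamma_NC", "gamma_CN", "gamma_CC", "tau_N", "tau_C",
                     "v", "z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlasmidState:
    """Named state of the plasmid model (densities per ml, R in µg/ml)."""

    N: float = 0.0
    N_P: float = 0.0
    C: float = 0.0
    C_P: float = 0.0
    C_X: float = 0.0
    R: float = 0.0

    def to_state_vector(self, t: float = 0.0) -> StateVector:
        return StateVector(
            labels=PLASMID_ROSTER,
            densities=np.array([self.N, self.N_P, self.C, self.C_P, self.C_X]),
            R=self.R,
            t=t,
        )


def plasmid_rhs(
    s: PlasmidState | np.ndarray,
    p: PlasmidParams,
    env: ChemostatEnv,
) -> np.ndarray:
    """Time derivatives ``(dN, dN_P, dC, dC_P, dC_X, dR)`` of the plasmid model."""
    if isinstance(s, PlasmidState):
        y = s.to_state_vector().as_array()
    else:
        y = np.asarray(s, dtype=float)
    N, N_P, C, C_P, C_X, R = y
    R = max(R, 0.0)

    psi_N = monod_growth(p.V_N, env.k, R)
    psi_NP = monod_growth(p.V_NP, env.k, R)
    psi_C = monod_growth(p.V_C, env.k, R)
    psi_CP = monod_growth(p.V_CP, env.k, R)
    psi_X = monod_growth(p.V_X, env.k, R)

    # mass-action transfer fluxes into the two plasmid-free recipients
    T_N = (p.gamma_NN * N_P + p.gamma_CN * C_P) * N
    T_C = (p.gamma_NC * N_P + p.gamma_CC * C_P) * C

    w = env.w
    z_X = p.z * C_X if p.z_on_CX else 0.0
    dN = psi_N * N - T_N + p.tau_N * N_P + p.z * C + z_X - w * N
    dN_P = psi_NP * N_P + T_N - p.tau_N * N_P + p.z * C_P - w * N_P
    dC = psi_C * C - T_C + p.tau_C * C_P + p.v * C_X - p.z * C - w * C
    dC_P = psi_CP * C_P + (1.0 - p.m) * T_C - p.tau_C * C_P - p.z * C_P - w * C_P
    dC_X = psi_X * C_X + p.m * T_C - p.v * C_X - z_X - w * C_X
    dR = w * (env.A - R) - env.e * (
        psi_N * N + psi_NP * N_P + psi_C * C + psi_CP * C_P + psi_X * C_X
    )
    return np.array([dN, dN_P, dC, dC_P, dC_X, dR])


def simulate_plasmid(
    p: PlasmidParams,
    env: ChemostatEnv,
    initial: PlasmidState,
    t_end: float,
    **integrate_kwargs,
) -> Trajectory:
    """Integrate the plasmid model from ``initial`` to ``t_end`` hours."""
    return integrate(
        lambda t, y: plasmid_rhs(y, p, env),
        initial.to_state_vector(),
        env,
        t_end,
        **integrate_kwargs,
    )
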