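"""Lytic-phage model: chemostat dynamics of CRISPR immunity against a virus.

Five populations share the vessel with the resource R:

* ``N``   — phage-sensitive non-CRISPR bacteria,
* ``N_R`` — envelope-resistant non-CRISPR bacteria (phage cannot adsorb),
* ``C``   — phage-sensitive CRISPR bacteria (no matching spacer yet),
* ``C_R`` — phage-immune CRISPR bacteria,
* ``P``   — free lytic phage.

Phage adsorb to N and C with mass-action rate constants ``delta_N`` and
``delta_C``.  A fraction ``m`` of infections of C are aborted and yield an
immune C_R cell; the rest burst.  Immune C_R cells soak up phage at the
maximum adsorption rate ``delta_MAX``, but are only *killed* (and produce
phage) at an effective rate that rises with the multiplicity of infection
(MOI) ``M = P/C_R``: at low MOI immunity holds (rate ``delta_MIN``), at high
MOI the immune machinery is overwhelmed and the effective killing rate
saturates at ``delta_MIN + x·(delta_MAX − delta_MIN)``.  Immunity is lost at
rate ``v`` (C_R→C), and sensitive non-CRISPR cells mutate to envelope
resistance at rate ``mu`` (N→N_R).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import ChemostatEnv, StateVector, Trajectory, integrate, monod_growth

__all__ = [
    "PHAGE_ROSTER",
    "PhageParams",
    "PhageState",
    "moi",
    "effective_adsorption",
    "phage_rhs",
    "simulate_phage",
]

#: Population labels in roster (column) order.
PHAGE_ROSTER: tuple[str, ...] = ("N", "N_R", "C", "C_R", "P")

#: Guard density for the MOI ratio when C_R vanishes (cells/ml).
MOI_GUARD = 1.0


@dataclass(frozen=True)
class PhageParams:
    """Complete parameter set of the phage model.

    Growth rates are hr⁻¹; adsorption rate constants are ml per phage–cell
    pair per hour; burst sizes are phage per lysed cell, net of the adsorbed
    particle.  ``mutation_growth_coupled`` selects whether the N→N_R mutation
    flux is ``mu·ψ_N·N`` (per division, default) or ``mu·N`` (per hour).
    """

    V_N: float = 1.0
    V_NR: float = 0.85
    V_C: float = 0.95
    V_CR: float = 0.90
    delta_N: float = 5e-9
    delta_C: float = 5e-9
    delta_MIN: float = 1e-14
    delta_MAX: float = 5e-9
    x: float = 0.0
    q: float = 1e2
    n: float = 2.0
    beta_N: float = 80.0
    beta_C: float = 80.0
    beta_CR: float = 80.0
    mu: float = 1e-8
    m: float = 0.1
    v: float = 1e-3
    mutation_growth_coupled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("MOI-effect magnitude x must lie in [0, 1]")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("abortive-infection probability m must lie in [0, 1]")
        if self.delta_MIN > self.delta_MAX:
            raise ValueError("delta_MIN must not exceed delta_MAX")
        for name in ("V_N", "V_NR", "V_C", "V_CR", "delta_N", "delta_C",
                     "delta_MIN", "delta_MAX", "q", "n", "beta_N", "beta_C",
                     "beta_CR", "mu", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhageState:
    """Named state of the phage model (densities per ml, R in µg/ml)."""

    N: float = 0.0
    N_R: float = 0.0
    C: float = 0.0
    C_R: float = 0.0
    P: float = 0.0
    R: float = 0.0

    def to_state_vector(self, t: float = 0.0) -> StateVector:
        return StateVector(
            labels=PHAGE_ROSTER,
            densities=np.array([self.N, self.N_R, self.C, self.C_R, self.P]),
            R=self.R,
            t=t,
        )


def moi(P: float, C_R: float) -> float:
    """Multiplicity of infection ``M = P/C_R``, guarded near ``C_R = 0``.

    When C_R falls below 1 cell/ml the ratio is evaluated at 1 cell/ml, so M
    stays finite and the killing term ``δ(M)·C_R·P`` vanishes smoothly with
    C_R.
    """
    if P < 0 or C_R < 0:
        raise ValueError("densities must be nonnegative")
    return P / max(C_R, MOI_GUARD)


def effective_adsorption(M: float, p: PhageParams) -> float:
    """MOI-dependent effective killing rate of phage on immune C_R cells.

    A Hill function of the MOI,

        δ(M) = δ_MIN + x·(δ_MAX − δ_MIN)·Mⁿ/(qⁿ + Mⁿ),

    rising from ``delta_MIN`` at M=0 to ``delta_MIN + x·(delta_MAX−delta_MIN)``
    as M→∞, with half-maximal MOI effect at ``M = q``.
    """
    if M < 0:
        raise ValueError("MOI must be nonnegative")
    if M == 0.0 or p.x == 0.0:
        return p.delta_MIN
    mn = M**p.n
    return p.delta_MIN + p.x * (p.delta_MAX - p.delta_MIN) * mn / (p.q**p.n + mn)


def phage_rhs(
    s: PhageState | np.ndarray,
    p: PhageParams,
    env: ChemostatEnv,
) -> np.ndarray:
    """Time derivatives ``(dN, dN_R, dC, dC_R, dP, dR)`` of the phage model.

    Accepts a :class:`PhageState` or a raw array in roster order plus R.
    Adsorption terms onto a host population are switched off while that
    population is below the refuge density.
    """
    if isinstance(s, PhageState):
        y = s.to_state_vector().as_array()
    else:
        y = np.asarray(s, dtype=float)
    N, N_R, C, C_R, P, R = y
    R = max(R, 0.0)

    psi_N = monod_growth(p.V_N, env.k, R)
    psi_NR = monod_growth(p.V_NR, env.k, R)
    psi_C = monod_growth(p.V_C, env.k, R)
    psi_CR = monod_growth(p.V_CR, env.k, R)

    # refuge: phage adsorb only to the excess host density above the refuge
    ads_N = p.delta_N * env.adsorbable_density(N) * P
    ads_C = p.delta_C * env.adsorbable_density(C) * P
    CR_ads = env.adsorbable_density(C_R)
    delta_CR = effective_adsorption(moi(max(P, 0.0), max(C_R, 0.0)), p)
    kill_CR = delta_CR * CR_ads * P
    sink_CR = p.delta_MAX * CR_ads * P

    if p.mutation_growth_coupled:
        mut = p.mu * psi_N * N
    else:
        mut = p.mu * N

    w = env.w
    dN = psi_N * N - mut - ads_N - w * N
    dN_R = psi_NR * N_R + mut - w * N_R
    dC = psi_C * C - ads_C + p.v * C_R - w * C
    dC_R = psi_CR * C_R + p.m * ads_C - kill_CR - p.v * C_R - w * C_R
    dP = (
        p.beta_N * ads_N
        + p.beta_C * (1.0 - p.m) * ads_C
        - p.m * ads_C
        + p.beta_CR * kill_CR
        - sink_CR
        - w * P
    )
    dR = w * (env.A - R) - env.e * (
        psi_N * N + psi_NR * N_R + psi_C * C + psi_CR * C_R
    )
    return np.array([dN, dN_R, dC, dC_R, dP, dR])


def simulate_phage(
    p: PhageParams,
    env: ChemostatEnv,
    initial: PhageState,
    t_end: float,
    **integrate_kwargs,
) -> Trajectory:
    """Integrate the phage model from ``initial`` to ``t_end`` hours.

    The phage-extinction event (total P below the environment threshold at a
    reported step ⇒ P set to zero) and per-population refuge-crossing events
    are logged on the returned :class:`~crisprdyn.core.Trajectory`.
    """
    return integrate(
        lambda t, y: phage_rhs(y, p, env),
        initial.to_state_vector(),
        env,
        t_end,
        phage_labels=("P",),
        refuge_labels=("N", "C", "C_R"),
        **integrate_kwargs,
    )
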