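"""Shared chemostat habitat model, growth kinetics, state containers and the
integration contract used by both the phage and the plasmid models.

The habitat is a continuous culture (chemostat) of unit volume (1 ml): medium
with the limiting resource at concentration ``A`` µg/ml flows in at dilution
rate ``w`` hr⁻¹ and everything — cells, phage, excess resource — washes out at
the same rate.  Bacterial growth follows Monod kinetics with maximum rate ``V``
and half-saturation constant ``k``; resource is consumed in proportion to
growth through the conversion efficiency ``e`` (µg per new cell).

Two numerical conventions specific to phage runs live here as well:

* a *refuge density*: adsorption onto a host population is switched off while
  that population sits below ``refuge_density`` cells/ml, which bounds the
  predator–prey oscillations;
* a *phage extinction threshold*: once total phage density falls below
  ``phage_extinction_threshold`` particles/ml at a reported step the phage are
  declared lost, set to exactly zero and the event is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import ode

__all__ = [
    "ChemostatEnv",
    "StateVector",
    "Trajectory",
    "IntegrationError",
    "monod_growth",
    "resource_flux",
    "integrate",
]


@dataclass(frozen=True)
class ChemostatEnv:
    """Habitat parameters shared by both models.

    Parameters
    ----------
    A : float
        Resource concentration in the reservoir (µg/ml).
    w : float
        Dilution (washout) rate (hr⁻¹).
    k : float
        Monod constant: resource concentration at half-maximal growth (µg/ml).
    e : float
        Conversion efficiency (µg of resource per cell produced).
    refuge_density : float
        Host density (cells/ml) below which phage cannot adsorb to that host
        population.
    phage_extinction_threshold : float
        Phage density (particles/ml) below which the phage population is set
        to zero at reported steps.
    """

    A: float = 50.0
    w: float = 0.2
    k: float = 0.25
    e: float = 5e-7
    refuge_density: float = 1e2
    phage_extinction_threshold: float = 1e-1

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("reservoir concentration A must be positive")
        if self.w < 0:
            raise ValueError("dilution rate w must be nonnegative")
        if self.k <= 0:
            raise ValueError("Monod constant k must be positive")
        if self.e <= 0:
            raise ValueError("conversion efficiency e must be positive")
        if self.refuge_density < 0:
            raise ValueError("refuge density must be nonnegative")
        if self.phage_extinction_threshold < 0:
            raise ValueError("phage extinction threshold must be nonnegative")

    def adsorbable_density(self, host_density: float) -> float:
        """Host density exposed to phage adsorption: the excess above the
        refuge, ``max(host − refuge_density, 0)``.

        Zero while the population sits inside the refuge.  The excess form
        (rather than an on/off switch at the refuge boundary) keeps the
        right-hand side continuous: with an on/off switch the solver chatters
        on a sliding mode when predation pins a host population exactly at
        the refuge density.
        """
        return max(host_density - self.refuge_density, 0.0)


def monod_growth(V: float, k: float, R: float):
    """Realized growth rate ``V·R/(k+R)`` (hr⁻¹) at resource concentration R.

    Monotone nondecreasing in ``R``, bounded above by ``V``; equals ``V/2`` at
    ``R = k`` (the definition of the Monod constant).
    """
    if V < 0:
        raise ValueError("maximum growth rate V must be nonnegative")
    if k <= 0:
        raise ValueError("Monod constant k must be positive")
    if np.any(np.asarray(R) < 0):
        raise ValueError("resource concentration R must be nonnegative")
    return V * R / (k + R)


def resource_flux(
    env: ChemostatEnv,
    R: float,
    growth_terms: Sequence[tuple[float, float]],
) -> float:
    """dR/dt (µg/ml/hr): inflow ``w(A−R)`` minus uptake ``e·Σ ψᵢ·Xᵢ``.

    ``growth_terms`` is a sequence of ``(realized growth rate ψᵢ, density Xᵢ)``
    pairs, one per bacterial population.
    """
    uptake = sum(psi * X for psi, X in growth_terms)
    return env.w * (env.A - R) - env.e * uptake


@dataclass
class StateVector:
    """Labeled population densities plus resource concentration at one time.

    ``labels`` names the populations of the active model in roster order;
    ``densities`` holds the matching values (cells/ml or, for phage,
    particles/ml).  ``R`` is the resource concentration (µg/ml) and ``t`` the
    time in hours.
    """

    labels: tuple[str, ...]
    densities: np.ndarray
    R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (len(self.labels),):
            raise ValueError("densities must match labels one-to-one")
        if np.any(self.densities < 0):
            raise ValueError("population densities must be nonnegative")
        if self.R < 0:
            raise ValueError("resource concentration must be nonnegative")

    def __getitem__(self, label: str) -> float:
        if label == "R":
            return self.R
        return float(self.densities[self.labels.index(label)])

    def as_array(self) -> np.ndarray:
        """Populations in roster order followed by R."""
        return np.append(self.densities, self.R)

    @classmethod
    def from_array(
        cls, labels: tuple[str, ...], y: np.ndarray, t: float
    ) -> "StateVector":
        y = np.asarray(y, dtype=float)
        return cls(labels=labels, densities=y[:-1], R=float(y[-1]), t=t)


@dataclass
class Trajectory:
    """Time-ordered solution of one simulation run.

    ``states`` has one row per reported time, columns in the order
    (populations in roster order, R).  ``events`` is a list of
    ``(time, event name)`` pairs, e.g. ``(312.5, "phage_extinct")``.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    states: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.labels + ("R",)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, self.columns.index(label)]

    @property
    def final(self) -> StateVector:
        return StateVector.from_array(
            self.labels, self.states[-1], float(self.times[-1])
        )

    def event_times(self, name: str) -> list[float]:
        return [t for t, n in self.events if n == name]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per reported time: t, R, populations, then event flags.

        Each distinct event name becomes a 0/1 column flagging the reported
        rows at or after the time the event (first) fired.
        """
        df = pd.DataFrame({"t": self.times, "R": self["R"]})
        for lab in self.labels:
            df[lab] = self[lab]
        for name in dict.fromkeys(n for _, n in self.events):
            t0 = min(self.event_times(name))
            df[f"event_{name}"] = (self.times >= t0).astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None, log: bool = True):
        """Convenience density-vs-time plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lab in self.labels:
            ax.plot(self.times, np.maximum(self[lab], 1e-2), label=lab)
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("time (hr)")
        ax.set_ylabel("density (per ml)")
        ax.legend()
        return ax


class IntegrationError(RuntimeError):
    """Solver failure; carries the trajectory up to the last valid state."""

    def __init__(self, message: str, partial: Trajectory):
        super().__init__(message)
        self.partial = partial


def integrate(
    model_rhs: Callable[[float, np.ndarray], np.ndarray],
    initial: StateVector,
    env: ChemostatEnv,
    t_end: float,
    report_dt: float = 0.5,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    phage_labels: tuple[str, ...] = (),
    refuge_labels: tuple[str, ...] = (),
) -> Trajectory:
    """Integrate ``model_rhs`` from ``initial`` to ``t_end``.

    ``model_rhs(t, y)`` takes the raw state array (populations then R) and
    returns its derivative.  States are reported every ``report_dt`` hours with
    densities floored at zero; the solver itself runs on the raw densities.

    Event handling, applied at reported steps only:

    * if the summed density over ``phage_labels`` drops below
      ``env.phage_extinction_threshold`` the phage states are set to exactly
      zero and ``"phage_extinct"`` is logged (once);
    * a ``"refuge_<label>"`` event is logged each time a population in
      ``refuge_labels`` crosses below ``env.refuge_density`` from above.

    ``method`` is ``"lsoda"`` (stiff-capable, default) or ``"dopri5"``
    (explicit Runge–Kutta).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if report_dt <= 0:
        raise ValueError("report_dt must be positive")
    if method not in ("lsoda", "dopri5"):
        raise ValueError(f"unknown integration method {method!r}")

    labels = initial.labels
    n_pop = len(labels)
    phage_idx = [labels.index(p) for p in phage_labels]
    refuge_idx = [labels.index(p) for p in refuge_labels]

    t0 = initial.t
    times = [t0]
    y = initial.as_array().copy()
    events: list[tuple[float, str]] = []
    phage_extinct = False

    def apply_events(t: float, y: np.ndarray, y_prev: np.ndarray | None) -> bool:
        """Mutates y in place; returns True if the solver must be restarted."""
        nonlocal phage_extinct
        restart = False
        if phage_idx and not phage_extinct:
            if sum(y[i] for i in phage_idx) < env.phage_extinction_threshold:
                for i in phage_idx:
                    y[i] = 0.0
                events.append((t, "phage_extinct"))
                phage_extinct = True
                restart = True
        if phage_extinct:
            for i in phage_idx:
                y[i] = 0.0
        if y_prev is not None:
            for i in refuge_idx:
                if y[i] < env.refuge_density <= y_prev[i]:
                    events.append((t, f"refuge_{labels[i]}"))
        return restart

    apply_events(t0, y, None)
    rows = [np.maximum(y, 0.0)]

    if method == "lsoda":
        solver = ode(model_rhs).set_integrator(
            "lsoda", rtol=rtol, atol=atol, nsteps=100000
        )
    else:
        solver = ode(model_rhs).set_integrator(
            "dopri5", rtol=rtol, atol=atol, nsteps=100000
        )
    solver.set_initial_value(y.copy(), t0)

    n_steps = int(round((t_end - t0) / report_dt))
    report_times = t0 + report_dt * np.arange(1, n_steps + 1)
    if report_times.size == 0 or report_times[-1] < t_end - 1e-12:
        report_times = np.append(report_times, t_end)

    for t_next in report_times:
        y_prev = rows[-1]
        solver.integrate(t_next)
        if not solver.successful():
            partial = Trajectory(labels, np.array(times), np.array(rows), events)
            raise IntegrationError(
                f"ODE solver failed at t={solver.t:.3f} hr", partial
            )
        y = np.array(solver.y, dtype=float)
        if apply_events(t_next, y, y_prev):
            solver.set_initial_value(y.copy(), t_next)
        times.append(t_next)
        rows.append(np.maximum(y, 0.0))

    return Trajectory(labels, np.array(times), np.array(rows), events)
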