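"""End-state classification of simulation runs.

The models' predictions are regimes, not single numbers: which population
dominates, who persists, whether the phage survive, and whether the bacterial
community at large is held in check by resource scarcity (resource-limited:
R drawn down near its equilibrium value) or by phage predation (phage-limited:
bacteria kept so sparse that resource stays near the reservoir concentration).
Because the dynamics oscillate persistently, all quantities are means over a
final evaluation window rather than instantaneous values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = ["ClassifierSettings", "OutcomeSummary", "classify"]

#: Label of the phage population in phage-model rosters.
PHAGE_LABEL = "P"


@dataclass(frozen=True)
class ClassifierSettings:
    """Knobs of the outcome classifier.

    ``window_fraction``: final fraction of the run over which means are taken.
    ``persistence_floor``: mean density (per ml) above which a population
    counts as persisting.  ``limitation_fraction``: the community is called
    phage-limited when mean resource exceeds this fraction of the reservoir
    concentration ``A``.  ``extinction_threshold``: final phage density that
    must be exceeded for the phage to count as persisting.
    """

    window_fraction: float = 0.2
    persistence_floor: float = 1.0
    limitation_fraction: float = 0.5
    A: float = 50.0
    extinction_threshold: float = 1e-1


@dataclass
class OutcomeSummary:
    """Classified end state of one run."""

    dominant: str | None
    persisting: list[str]
    phage_persisted: bool
    regime: str  # "resource-limited" | "phage-limited" | "washout"
    mean_densities: dict = field(default_factory=dict)
    final_R: float = 0.0
    events: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dominant": self.dominant,
            "persisting": self.persisting,
            "phage_persisted": self.phage_persisted,
            "regime": self.regime,
            "mean_densities": self.mean_densities,
            "final_R": self.final_R,
            "events": [[t, name] for t, name in self.events],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def classify(
    traj: Trajectory, settings: ClassifierSettings = ClassifierSettings()
) -> OutcomeSummary:
    """Summarize a trajectory into an :class:`OutcomeSummary`.

    Means are taken over the final ``window_fraction`` of the simulated span.
    The dominant population is the persisting one with the highest mean
    density; with no persisting bacterial population the run is classified as
    washout.  Raises ``ValueError`` if the trajectory is too short to contain
    the evaluation window.
    """
    times = traj.times
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("trajectory must span a positive time interval")
    window_start = times[-1] - settings.window_fraction * span
    mask = times >= window_start
    if mask.sum() < 3:
        raise ValueError(
            "trajectory too short: evaluation window holds fewer than 3 points"
        )

    mean_densities = {
        lab: float(np.mean(traj[lab][mask])) for lab in traj.labels
    }
    mean_R = float(np.mean(traj["R"][mask]))

    persisting = [
        lab for lab in traj.labels
        if mean_densities[lab] > settings.persistence_floor
    ]
    dominant = max(persisting, key=lambda lab: mean_densities[lab], default=None)

    has_phage = PHAGE_LABEL in traj.labels
    phage_persisted = bool(
        has_phage
        and not traj.event_times("phage_extinct")
        and traj.final[PHAGE_LABEL] > settings.extinction_threshold
    )

    bacterial = [lab for lab in persisting if lab != PHAGE_LABEL]
    if not bacterial:
        regime = "washout"
    elif mean_R > settings.limitation_fraction * settings.A:
        regime = "phage-limited"
    else:
        regime = "resource-limited"

    return OutcomeSummary(
        dominant=dominant,
        persisting=persisting,
        phage_persisted=phage_persisted,
        regime=regime,
        mean_densities=mean_densities,
        final_R=mean_R,
        events=list(traj.events),
    )
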