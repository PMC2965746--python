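"""Named scenario presets reproducing the simulation figures, and the runner.

Each preset fixes a complete, fully explicit parameter set: habitat, model
parameters, initial densities, and integration settings.  Values printed in
the corresponding figure caption carry that caption as provenance; everything
the caption omits is flagged ``default`` in the serialized config echo.

Invasion scenarios start residents at their analytic chemostat equilibrium,
invaders at 1e3 cells/ml, and phage (where introduced) at 1e4 particles/ml.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .analytics import (
    bacterial_equilibrium,
    phage_coexistence_equilibrium,
    resource_equilibrium,
)
from .config import ConfigError, ScenarioConfig, serialize
from .core import ChemostatEnv, Trajectory
from .outcomes import ClassifierSettings, OutcomeSummary, classify
from .phage import PhageParams, PhageState, simulate_phage
from .plasmid import PlasmidParams, PlasmidState, simulate_plasmid

__all__ = [
    "PRESET_NAMES",
    "build_preset",
    "run_config",
    "run_preset",
]

log = logging.getLogger("crisprdyn")

_ENV_PROV = {
    "env.A": "Fig 4 caption: A = 50 ug/ml (all simulations)",
    "env.w": "Fig 4 caption: w = 0.2 per hour",
    "env.k": "Fig 4 caption: k = 0.25 ug",
    "env.e": "Fig 4 caption: e = 5e-7 ug",
    "env.refuge_density": "default (refuge density, bounds oscillations)",
    "env.phage_extinction_threshold":
        "phage loss threshold 1e-1 particles/ml (numerical-solutions rule)",
}

_INTEG_PROV = {
    "integration.t_end": "preset horizon, hr",
    "integration.report_dt": "default report interval, hr",
    "integration.method": "default stiff-capable solver",
    "integration.rtol": "default relative tolerance",
    "integration.atol": "default absolute tolerance",
}

#: invasion initial densities (design defaults)
INVADER_DENSITY = 1e3
PHAGE_INOCULUM = 1e4


def _env_dict() -> dict:
    env = ChemostatEnv()
    return {
        "A": env.A, "w": env.w, "k": env.k, "e": env.e,
        "refuge_density": env.refuge_density,
        "phage_extinction_threshold": env.phage_extinction_threshold,
    }


def _integration_dict(t_end: float) -> dict:
    return {
        "t_end": t_end, "report_dt": 0.5, "method": "lsoda",
        "rtol": 1e-8, "atol": 1e-10,
    }


def _phage_config(
    preset: str,
    caption: str,
    param_overrides: dict,
    caption_keys: set,
    initial: dict,
    initial_prov: dict,
    t_end: float = 500.0,
) -> ScenarioConfig:
    params = PhageParams(**param_overrides).to_dict()
    prov = dict(_ENV_PROV)
    prov.update(_INTEG_PROV)
    prov["model.name"] = caption
    for key in params:
        if key in caption_keys:
            prov[f"params.{key}"] = caption
        else:
            prov[f"params.{key}"] = "default"
    for key, why in initial_prov.items():
        prov[f"initial.{key}"] = why
    return ScenarioConfig(
        model="phage",
        env=_env_dict(),
        params=params,
        initial=initial,
        integration=_integration_dict(t_end),
        preset=preset,
        provenance=prov,
    )


def _plasmid_config(
    preset: str,
    caption: str,
    param_overrides: dict,
    caption_keys: set,
    initial: dict,
    initial_prov: dict,
    t_end: float = 2000.0,
) -> ScenarioConfig:
    params = PlasmidParams(**param_overrides).to_dict()
    prov = dict(_ENV_PROV)
    prov.update(_INTEG_PROV)
    prov["model.name"] = caption
    for key in params:
        if key in caption_keys:
            prov[f"params.{key}"] = caption
        else:
            prov[f"params.{key}"] = "default"
    for key, why in initial_prov.items():
        prov[f"initial.{key}"] = why
    return ScenarioConfig(
        model="plasmid",
        env=_env_dict(),
        params=params,
        initial=initial,
        integration=_integration_dict(t_end),
        preset=preset,
        provenance=prov,
    )


def _resident_equilibrium(V: float) -> tuple[float, float]:
    env = ChemostatEnv()
    return bacterial_equilibrium(env, V), resource_equilibrium(V, env.k, env.w)


def _fig4a() -> ScenarioConfig:
    cap = "Fig 4a caption: V_N = 1.0/hr, delta_N = 5e-9; no CRISPR"
    N_star, R_star = _resident_equilibrium(1.0)
    return _phage_config(
        "fig4a", cap,
        {"V_N": 1.0, "delta_N": 5e-9, "mu": 0.0, "m": 0.0},
        {"V_N", "delta_N"},
        {"N": N_star, "N_R": 0.0, "C": 0.0, "C_R": 0.0,
         "P": PHAGE_INOCULUM, "R": R_star},
        {"N": "resident at analytic equilibrium",
         "P": "phage inoculum (default 1e4/ml)",
         "R": "resource at resident equilibrium"},
    )


def _phage_resident_community(params: PhageParams) -> tuple[float, float, float]:
    """Resident N/phage pair at its analytic coexistence equilibrium."""
    env = ChemostatEnv()
    return phage_coexistence_equilibrium(
        env, params.V_N, params.delta_N, params.beta_N
    )


def _fig4_invasion(preset: str, cap: str, x: float) -> ScenarioConfig:
    overrides = {
        "V_N": 1.0, "V_C": 0.95, "V_CR": 0.90,
        "delta_N": 5e-9, "delta_C": 5e-9,
        "delta_MIN": 1e-14, "delta_MAX": 5e-9,
        "x": x, "q": 1e2, "n": 2.0,
        "mu": 0.0,
    }
    caption_keys = {"V_N", "V_C", "V_CR", "delta_N", "delta_C",
                    "delta_MIN", "delta_MAX", "x"}
    if x > 0:
        caption_keys |= {"q", "n"}
    N_star, P_star, R_star = _phage_resident_community(PhageParams(**overrides))
    return _phage_config(
        preset, cap, overrides, caption_keys,
        {"N": N_star, "N_R": 0.0, "C": INVADER_DENSITY, "C_R": 0.0,
         "P": P_star, "R": R_star},
        {"N": "resident N at N/phage coexistence equilibrium",
         "C": "rare CRISPR invader (default 1e3/ml)",
         "P": "resident phage at N/phage coexistence equilibrium",
         "R": "resource at N/phage coexistence equilibrium"},
    )


def _fig5(preset: str, cap: str, V_NR: float) -> ScenarioConfig:
    overrides = {
        "V_N": 1.0, "V_NR": V_NR, "V_C": 0.95, "V_CR": 0.90,
        "delta_N": 5e-9, "delta_C": 5e-9,
        "delta_MIN": 1e-14, "delta_MAX": 5e-9,
        "x": 0.0,
    }
    N_star, P_star, R_star = _phage_resident_community(PhageParams(**overrides))
    return _phage_config(
        preset, cap, overrides,
        {"V_N", "V_NR", "V_C", "V_CR", "delta_N", "delta_C",
         "delta_MIN", "delta_MAX"},
        {"N": N_star, "N_R": INVADER_DENSITY, "C": INVADER_DENSITY,
         "C_R": 0.0, "P": P_star, "R": R_star},
        {"N": "resident N at N/phage coexistence equilibrium",
         "N_R": "rare envelope-resistant invader (default 1e3/ml)",
         "C": "rare CRISPR invader (default 1e3/ml)",
         "P": "resident phage at N/phage coexistence equilibrium",
         "R": "resource at N/phage coexistence equilibrium"},
    )


_FIG6_CAPTION = (
    "Fig 6 caption: gammas = 1e-9, tau_N = tau_C = 1e-3, v = 1e-3, "
    "m = 0.2, z = 1e-8"
)


def _fig6a(preset: str, cap: str, V_NP: float, gamma_NN: float = 1e-9
           ) -> ScenarioConfig:
    N_star, R_star = _resident_equilibrium(1.0)
    caption_keys = {"V_N", "V_NP", "gamma_NN", "gamma_NC", "gamma_CN",
                    "gamma_CC", "tau_N", "tau_C", "v", "m", "z"}
    return _plasmid_config(
        preset, cap,
        {"V_N": 1.0, "V_NP": V_NP, "gamma_NN": gamma_NN},
        caption_keys,
        {"N": N_star, "N_P": INVADER_DENSITY, "C": 0.0, "C_P": 0.0,
         "C_X": 0.0, "R": R_star},
        {"N": "resident at analytic equilibrium",
         "N_P": "rare plasmid-bearing invader (default 1e3/ml)",
         "R": "resource at resident equilibrium"},
    )


_FIG6BCD_V = {"V_N": 1.0, "V_C": 0.97, "V_X": 0.96}


def _fig6b() -> ScenarioConfig:
    cap = ("Fig 6b caption: V_N = 1, V_NP = 0.95, V_C = 0.97, V_CP = 0.88, "
           "V_X = 0.96; " + _FIG6_CAPTION)
    C_star, R_star = _resident_equilibrium(0.97)
    return _plasmid_config(
        "fig6b", cap,
        dict(_FIG6BCD_V, V_NP=0.95, V_CP=0.88),
        {"V_N", "V_NP", "V_C", "V_CP", "V_X", "gamma_NN", "gamma_NC",
         "gamma_CN", "gamma_CC", "tau_N", "tau_C", "v", "m", "z"},
        {"N": 0.0, "N_P": INVADER_DENSITY, "C": C_star, "C_P": 0.0,
         "C_X": 0.0, "R": R_star},
        {"C": "resident CRISPR population at analytic equilibrium",
         "N_P": "rare plasmid-bearing invader (default 1e3/ml)",
         "R": "resource at resident equilibrium"},
    )


#: burn-in horizon used to put the N/N_P pair at its joint equilibrium (hr)
_FIG6C_BURN_IN = 1500.0


def _fig6c() -> ScenarioConfig:
    cap = ("Fig 6c caption: invasion of immune CRISPR into an N/N_P "
           "equilibrium; parameters as Fig 6b")
    params = PlasmidParams(**dict(_FIG6BCD_V, V_NP=0.95, V_CP=0.88))
    env = ChemostatEnv()
    N_star, R_star = _resident_equilibrium(1.0)
    burn = simulate_plasmid(
        params, env,
        PlasmidState(N=N_star, N_P=INVADER_DENSITY, R=R_star),
        t_end=_FIG6C_BURN_IN,
    )
    final = burn.final
    return _plasmid_config(
        "fig6c", cap,
        dict(_FIG6BCD_V, V_NP=0.95, V_CP=0.88),
        {"V_N", "V_NP", "V_C", "V_CP", "V_X", "gamma_NN", "gamma_NC",
         "gamma_CN", "gamma_CC", "tau_N", "tau_C", "v", "m", "z"},
        {"N": final["N"], "N_P": final["N_P"], "C": 0.0, "C_P": 0.0,
         "C_X": INVADER_DENSITY, "R": final["R"]},
        {"N": f"N/N_P joint equilibrium (burn-in {_FIG6C_BURN_IN:g} hr)",
         "N_P": f"N/N_P joint equilibrium (burn-in {_FIG6C_BURN_IN:g} hr)",
         "C_X": "rare immune CRISPR invader (default 1e3/ml)",
         "R": f"resource after burn-in {_FIG6C_BURN_IN:g} hr"},
    )


def _fig6d() -> ScenarioConfig:
    cap = ("Fig 6d caption: beneficial plasmid, V_N = 1, V_NP = 1.2, "
           "V_C = 0.97, V_CP = 1.1, V_X = 0.96; " + _FIG6_CAPTION)
    C_star, R_star = _resident_equilibrium(0.97)
    return _plasmid_config(
        "fig6d", cap,
        dict(_FIG6BCD_V, V_NP=1.2, V_CP=1.1),
        {"V_N", "V_NP", "V_C", "V_CP", "V_X", "gamma_NN", "gamma_NC",
         "gamma_CN", "gamma_CC", "tau_N", "tau_C", "v", "m", "z"},
        {"N": 0.0, "N_P": INVADER_DENSITY, "C": C_star, "C_P": 0.0,
         "C_X": 0.0, "R": R_star},
        {"C": "resident CRISPR population at analytic equilibrium",
         "N_P": "rare plasmid-bearing invader (default 1e3/ml)",
         "R": "resource at resident equilibrium"},
    )


_BUILDERS = {
    "fig4a": _fig4a,
    "fig4b": lambda: _fig4_invasion(
        "fig4b",
        "Fig 4b caption: no MOI effect (x = 0), V_N = 1.0, V_C = 0.95, "
        "V_CR = 0.90, delta_N = delta_C = 5e-9, delta_MIN = 1e-14, "
        "delta_MAX = 5e-9",
        x=0.0),
    "fig4c": lambda: _fig4_invasion(
        "fig4c",
        "Fig 4c caption: strong MOI effect (x = 0.5, n = 2, q = 1e2), "
        "V_N = 1.0, V_C = 0.95, V_CR = 0.90, delta_N = delta_C = 5e-9, "
        "delta_MIN = 1e-14, delta_MAX = 5e-9",
        x=0.5),
    "fig4d": lambda: _fig4_invasion(
        "fig4d",
        "Fig 4d caption: modest MOI effect (x = 0.2, n = 2, q = 1e2), "
        "V_N = 1.0, V_C = 0.95, V_CR = 0.90, delta_N = delta_C = 5e-9, "
        "delta_MIN = 1e-14, delta_MAX = 5e-9",
        x=0.2),
    "fig5a": lambda: _fig5(
        "fig5a",
        "Fig 5a caption: modest cost of envelope resistance, V_NR = 0.85; "
        "other parameters as Fig 4",
        V_NR=0.85),
    "fig5b": lambda: _fig5(
        "fig5b",
        "Fig 5b caption: greater cost of envelope resistance, V_NR = 0.70; "
        "other parameters as Fig 4",
        V_NR=0.70),
    "fig6a1": lambda: _fig6a(
        "fig6a1",
        "Fig 6a-1 caption: deleterious plasmid, V_N = 1, V_NP = 0.95; "
        + _FIG6_CAPTION,
        V_NP=0.95),
    "fig6a2": lambda: _fig6a(
        "fig6a2",
        "Fig 6a-2 caption: beneficial plasmid, V_N = 1, V_NP = 1.2; "
        + _FIG6_CAPTION,
        V_NP=1.2),
    "fig6a3": lambda: _fig6a(
        "fig6a3",
        "Fig 6a-3 caption: deleterious plasmid, V_N = 1, V_NP = 0.95, "
        "gamma_NN = 1e-11; " + _FIG6_CAPTION,
        V_NP=0.95, gamma_NN=1e-11),
    "fig6b": _fig6b,
    "fig6c": _fig6c,
    "fig6d": _fig6d,
}

PRESET_NAMES: tuple[str, ...] = tuple(_BUILDERS)


def build_preset(name: str) -> ScenarioConfig:
    """Build the fully explicit config of a named preset."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return builder()


def run_config(cfg: ScenarioConfig) -> tuple[Trajectory, OutcomeSummary]:
    """Simulate a parsed config and classify its outcome."""
    env = ChemostatEnv(**cfg.env)
    integ = dict(cfg.integration)
    t_end = integ.pop("t_end")
    try:
        if cfg.model == "phage":
            params = PhageParams(**cfg.params)
            initial = PhageState(**cfg.initial)
            traj = simulate_phage(params, env, initial, t_end, **integ)
        else:
            params = PlasmidParams(**cfg.params)
            initial = PlasmidState(**cfg.initial)
            traj = simulate_plasmid(params, env, initial, t_end, **integ)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    settings = ClassifierSettings(
        A=env.A, extinction_threshold=env.phage_extinction_threshold
    )
    return traj, classify(traj, settings)


def run_preset(
    name: str,
    overrides: dict | None = None,
    out_dir: str | Path | None = None,
    t_end: float | None = None,
) -> tuple[Trajectory, OutcomeSummary, str]:
    """Run a named preset, optionally with overrides, and return
    ``(trajectory, outcome summary, serialized config echo)``.

    Overrides are bare ``key: value`` pairs resolved against the params, env,
    initial and integration sections in that order.  When ``out_dir`` is
    given, the config echo, CSV time series, JSON outcome summary and a run
    log are written there.
    """
    cfg = build_preset(name)
    if t_end is not None:
        cfg.integration["t_end"] = float(t_end)
        cfg.provenance["integration.t_end"] = "override"
    for key, value in (overrides or {}).items():
        cfg.set_override(key, value)
    echo = serialize(cfg)
    log.info("running preset %s (model=%s, t_end=%g hr)",
             name, cfg.model, cfg.integration["t_end"])
    traj, summary = run_config(cfg)
    log.info("preset %s: dominant=%s regime=%s events=%s",
             name, summary.dominant, summary.regime, summary.events)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.txt").write_text(echo)
        traj.to_csv(out / "timeseries.csv")
        (out / "outcome.json").write_text(summary.to_json())
        (out / "run.log").write_text(
            f"preset: {name}\nmodel: {cfg.model}\n"
            f"t_end: {cfg.integration['t_end']}\n"
            f"dominant: {summary.dominant}\nregime: {summary.regime}\n"
            f"events: {summary.events}\n"
        )
    return traj, summary, echo
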