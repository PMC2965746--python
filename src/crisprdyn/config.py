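"""Plain-text configuration files for simulation runs.

A run is described by a sectioned key–value file::

    [model]
    name = phage
    preset = fig4b

    [env]
    # reservoir resource concentration, ug/ml
    A = 50.0
    ...

    [params]
    ...

    [initial]
    ...

    [integration]
    t_end = 500.0
    ...

Keys use the ASCII parameter names of the model dataclasses (``delta_N``,
``beta_N``, ``gamma_NN``, ``tau_N``, ``V_N``, ...).  Comment lines (``# ...``)
immediately above a key document where its value comes from (a figure caption
or a package default); they are preserved through a parse/serialize round
trip, which is exact: ``serialize(parse(text)) == text`` for files this module
wrote.  The stdlib configparser is not used because it discards comments.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

__all__ = ["ConfigError", "ScenarioConfig", "serialize", "parse"]

SECTIONS = ("model", "env", "params", "initial", "integration")


class ConfigError(ValueError):
    """Malformed configuration text or unknown key/section."""


@dataclass
class ScenarioConfig:
    """Parsed run description: plain dictionaries, one per section.

    ``provenance`` maps ``"<section>.<key>"`` to a comment string recording
    where the value came from.
    """

    model: str
    env: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    integration: dict = field(default_factory=dict)
    preset: str | None = None
    provenance: dict = field(default_factory=dict)

    def section(self, name: str) -> dict:
        if name not in ("env", "params", "initial", "integration"):
            raise ConfigError(f"unknown section {name!r}")
        return getattr(self, name)

    def set_override(self, key: str, value) -> None:
        """Apply a bare ``key=value`` override, searching params, env,
        initial, integration in that order."""
        for name in ("params", "env", "initial", "integration"):
            sec = self.section(name)
            if key in sec:
                sec[key] = value
                self.provenance[f"{name}.{key}"] = "override"
                return
        raise ConfigError(f"unknown override key {key!r}")


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, numbers.Integral):
        return repr(int(v))
    if isinstance(v, numbers.Real):
        # repr of the builtin float round-trips exactly and also normalizes
        # numpy scalars, which would otherwise print as np.float64(...)
        return repr(float(v))
    return str(v)


def parse_value(text: str):
    """Parse a scalar: bool, int, float, or bare string."""
    t = text.strip()
    if t.lower() == "true":
        return True
    if t.lower() == "false":
        return False
    try:
        return int(t)
    except ValueError:
        pass
    try:
        return float(t)
    except ValueError:
        pass
    return t


def serialize(cfg: ScenarioConfig) -> str:
    """Render a :class:`ScenarioConfig` as sectioned key–value text."""
    lines: list[str] = []
    lines.append("[model]")
    if "model.name" in cfg.provenance:
        for c in cfg.provenance["model.name"].splitlines():
            lines.append(f"# {c}")
    lines.append(f"name = {cfg.model}")
    if cfg.preset:
        lines.append(f"preset = {cfg.preset}")
    for name in ("env", "params", "initial", "integration"):
        sec = cfg.section(name)
        lines.append("")
        lines.append(f"[{name}]")
        for key, value in sec.items():
            comment = cfg.provenance.get(f"{name}.{key}")
            if comment:
                for c in comment.splitlines():
                    lines.append(f"# {c}")
            lines.append(f"{key} = {_format_value(value)}")
    return "\n".join(lines) + "\n"


def parse(text: str) -> ScenarioConfig:
    """Parse sectioned key–value text into a :class:`ScenarioConfig`."""
    sections: dict[str, dict] = {name: {} for name in SECTIONS}
    provenance: dict[str, str] = {}
    current: str | None = None
    pending_comments: list[str] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            pending_comments = []
            continue
        if line.startswith("#"):
            pending_comments.append(line[1:].strip())
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            if current not in SECTIONS:
                raise ConfigError(f"line {lineno}: unknown section [{current}]")
            pending_comments = []
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        if current is None:
            raise ConfigError(f"line {lineno}: key outside of any section")
        key, _, value = line.partition("=")
        key = key.strip()
        sections[current][key] = parse_value(value)
        if pending_comments:
            provenance[f"{current}.{key}"] = "\n".join(pending_comments)
            pending_comments = []

    model_sec = sections["model"]
    if "name" not in model_sec:
        raise ConfigError("missing 'name' in [model] section")
    name = model_sec["name"]
    if name not in ("phage", "plasmid"):
        raise ConfigError(f"unknown model {name!r} (expected phage or plasmid)")
    prov = {k: v for k, v in provenance.items()}
    return ScenarioConfig(
        model=name,
        env=sections["env"],
        params=sections["params"],
        initial=sections["initial"],
        integration=sections["integration"],
        preset=model_sec.get("preset"),
        provenance=prov,
    )
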