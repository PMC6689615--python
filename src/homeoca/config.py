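"""Run configuration: a flat INI file that round-trips losslessly.

Sections:

``[params]``   r, d, a, g (g defaults to 1)
``[run]``      L, max_steps, sessions, base_seed, init, variant,
               snapshot_every, burn_in
``[variant.oscillatory]``  d0, amplitude, period
``[variant.threshold]``    quiescent_thresholded
``[output]``   out_dir

Unknown keys are rejected by name; parameter feasibility is validated on
load.
"""

from __future__ import annotations

import configparser
import hashlib
import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .params import Params, validate_params

_SCHEMA: dict[str, dict[str, type]] = {
    "params": {"r": float, "d": float, "a": float, "g": float},
    "run": {"L": int, "max_steps": int, "sessions": int, "base_seed": int,
            "init": str, "variant": str, "snapshot_every": int,
            "burn_in": int},
    "variant.oscillatory": {"d0": float, "amplitude": float, "period": float},
    "variant.threshold": {"quiescent_thresholded": bool},
    "output": {"out_dir": str},
}

_REQUIRED = {("params", "r"), ("params", "d"), ("params", "a"), ("run", "L")}

_VARIANTS = ("base", "oscillatory", "threshold")


@dataclass
class RunConfig:
    r: float
    d: float
    a: float
    L: int
    g: float = 1.0
    max_steps: int = 1000
    sessions: int = 1
    base_seed: int = 0
    init: str = "single"
    variant: str = "base"
    snapshot_every: int = 0
    burn_in: int = 0
    d0: float | None = None
    amplitude: float = 0.5
    period: float = 500.0
    quiescent_thresholded: bool = False
    out_dir: str = "."

    def params(self) -> Params:
        return Params(r=self.r, d=self.d, a=self.a, g=self.g)

    def validate(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        rep = validate_params(self.params())
        if not rep.ok:
            raise ValueError(
                "infeasible parameters: " + "; ".join(rep.messages())
            )

    # -- serialisation ------------------------------------------------

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp.optionxform = str  # keys are case-sensitive (L vs l)
        values = asdict(self)
        for section, keys in _SCHEMA.items():
            items = {}
            for key in keys:
                val = values[key]
                if val is None:
                    continue
                items[key] = str(val)
            if items:
                cp[section] = items
        buf = _io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    def save(self, path) -> None:
        Path(path).write_text(self.to_ini())

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for output metadata)."""
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]


def _parse_value(raw: str, typ: type):
    if typ is bool:
        low = raw.strip().lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return typ(raw)


def load_config(path) -> RunConfig:
    """Parse, validate and default-fill a configuration file.

    Raises ``ValueError`` with a distinct message for missing required
    keys, unknown keys (named), malformed values and infeasible
    parameters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cp = configparser.ConfigParser()
    cp.optionxform = str
    try:
        cp.read_string(path.read_text())
    except configparser.Error as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc

    unknown = []
    fields: dict[str, object] = {}
    for section in cp.sections():
        if section not in _SCHEMA:
            unknown.extend(f"[{section}]" for _ in [0])
            continue
        for key, raw in cp[section].items():
            if key not in _SCHEMA[section]:
                unknown.append(f"[{section}] {key}")
                continue
            try:
                fields[key] = _parse_value(raw, _SCHEMA[section][key])
            except ValueError as exc:
                raise ValueError(
                    f"malformed value for [{section}] {key}: {raw!r}"
                ) from exc
    if unknown:
        raise ValueError("unknown config keys: " + ", ".join(unknown))
    missing = [f"[{s}] {k}" for s, k in _REQUIRED
               if k not in fields]
    if missing:
        raise ValueError("missing required keys: " + ", ".join(missing))
    cfg = RunConfig(**fields)  # type: ignore[arg-type]
    cfg.validate()
    return cfg
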