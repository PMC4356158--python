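"""Configuration files, run manifests and small I/O helpers.

Simulation configuration is a flat key-value text file (``key = value`` per
line, ``#`` comments), with model parameters namespaced as ``model.*``::

    N = 100000
    mu = 1e-4
    T = 500
    model = fgm
    model.n = 10
    model.sigma = 0.05
    seed = 42
    record_every = 10
    replicates = 100

Every pipeline run writes a JSON manifest next to its outputs recording the
command, a digest of the resolved configuration, the seed, the package
version and the list of output files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .errors import InputError
from .models import (
    ModelSpec,
    declining_rate,
    diminishing_effects,
    fgm,
    finite_sites,
)
from .simulator import SimConfig


def parse_config_text(text: str) -> dict[str, str]:
    """Parse flat ``key = value`` lines into a string-valued dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"config line {lineno} is not 'key = value': {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise InputError(f"config line {lineno} has an empty key or value: {raw!r}")
        out[key] = value
    return out


def load_config(path) -> dict[str, str]:
    return parse_config_text(Path(path).read_text())


def _get(cfg: dict, key: str, cast, default=None):
    if key not in cfg:
        return default
    try:
        return cast(cfg[key])
    except ValueError as exc:
        raise InputError(f"config key {key!r} has invalid value {cfg[key]!r}") from exc


def build_model(cfg: dict[str, str]) -> ModelSpec:
    """Construct a ModelSpec from ``model`` and ``model.*`` config keys.

    A top-level ``mu`` key is shorthand for the model's baseline rate
    (``model.mu`` or ``model.mu0``); an explicit ``model.*`` key wins.
    """
    kind = cfg.get("model")
    if kind is None:
        raise InputError("config key 'model' is required")
    mu = _get(cfg, "model.mu", float, _get(cfg, "mu", float, 1e-5))
    g = _get(cfg, "model.g", float, 1.0)
    if kind == "diminishing_effects":
        return diminishing_effects(mu=mu, alpha0=_get(cfg, "model.alpha0", float, 50.0), g=g)
    if kind == "declining_rate":
        mu0 = _get(cfg, "model.mu0", float, _get(cfg, "mu", float, 1e-5))
        return declining_rate(mu0=mu0, alpha=_get(cfg, "model.alpha", float, 50.0), g=g)
    if kind == "finite_sites":
        return finite_sites(
            mu=mu,
            L=_get(cfg, "model.L", int, 100),
            alpha=_get(cfg, "model.alpha", float, 50.0),
        )
    if kind == "fgm":
        return fgm(
            mu=mu,
            n=_get(cfg, "model.n", int, 10),
            sigma=_get(cfg, "model.sigma", float, 0.05),
            decay=cfg.get("model.decay", "gaussian"),
        )
    raise InputError(f"unknown model kind {kind!r}")


def build_sim_config(cfg: dict[str, str], seed_override: int | None = None) -> SimConfig:
    seed = seed_override if seed_override is not None else _get(cfg, "seed", int)
    if seed is None:
        raise InputError("an RNG seed is required (config key 'seed' or --seed)")
    return SimConfig(
        N=_get(cfg, "N", int, 1_000_000),
        T=_get(cfg, "T", int, 500),
        model=build_model(cfg),
        seed=seed,
        record_every=_get(cfg, "record_every", int, 10),
        replicates=_get(cfg, "replicates", int, 1),
    )


def config_digest(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def write_manifest(out_dir, command: str, cfg: dict, seed: int | None, outputs: list[str]) -> Path:
    """Write the run manifest next to the outputs; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_digest(cfg),
        "seed": seed,
        "versions": {"macroepi": __version__},
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
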