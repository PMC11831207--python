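"""Configuration parsing, result serialization, and fixture generation.

Run configurations are single YAML files with four blocks::

    strategy:
      name: pdne1            # any name from strategies.strategy_names()
      idealized: true
      options: {}            # make_strategy keyword options / param overrides
    demography:
      Rm: 6.0
      dd_exponent: 1.0
    release:
      rho: 0.1
      cadence: every         # or single
      start: 0
      stop: null
    experiment:
      mode: timeseries       # timeseries | search | sweep | compare
      horizon: 40
      target: 0.95           # search/sweep/compare
      passage: first_passage # or at_horizon
      sweep: {variable: s_edit, grid: [1.0, 0.9, 0.8]}
      compare: [sit, ridl]   # strategies to compare against
    seed: null               # reserved; the engine is fully deterministic
    log_level: INFO

CSV outputs use '.' decimals with no locale dependence; every run writes a
JSON manifest recording the resolved parameters, the config SHA-256 hash
and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import yaml

from .demography import LifeCycle, ReleaseSchedule
from .genetics import ConfigError
from .strategies import StrategySpec, make_strategy, strategy_names

__all__ = ["RunConfig", "load_config", "write_manifest", "write_fixtures"]

_MODES = ("timeseries", "search", "sweep", "compare")


def _version() -> str:
    try:
        return metadata.version("drivebalance")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """A validated run configuration with resolved objects."""

    spec: StrategySpec
    lifecycle: LifeCycle
    release: ReleaseSchedule
    mode: str
    horizon: int
    target: float | None
    passage: str
    sweep: dict | None
    compare: list
    seed: object
    log_level: str
    raw: dict = field(repr=False, default_factory=dict)


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ConfigError(f"missing key {key!r} in {where!r} block")
    return block[key]


def parse_config(raw: dict) -> RunConfig:
    """Validate a configuration mapping and resolve it against the registry."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    sblock = _require(raw, "strategy", "top-level")
    name = _require(sblock, "name", "strategy")
    if name.lower().replace("-", "_") not in strategy_names():
        raise ConfigError(
            f"unknown strategy {name!r}; known: {', '.join(strategy_names())}"
        )
    options = dict(sblock.get("options") or {})
    spec = make_strategy(name, idealized=bool(sblock.get("idealized", True)),
                         **options)

    dblock = raw.get("demography") or {}
    lifecycle = LifeCycle(
        Rm=float(dblock.get("Rm", 6.0)),
        dd_exponent=float(dblock.get("dd_exponent", 1.0)),
    )

    rblock = raw.get("release") or {}
    stop = rblock.get("stop")
    release = ReleaseSchedule(
        genotype=spec.release_genotype,
        rho=float(rblock.get("rho", 0.0)),
        cadence=str(rblock.get("cadence", "every")),
        start=int(rblock.get("start", 0)),
        stop=None if stop is None else int(stop),
    )

    eblock = raw.get("experiment") or {}
    mode = str(eblock.get("mode", "timeseries"))
    if mode not in _MODES:
        raise ConfigError(f"unknown experiment mode {mode!r}")
    target = eblock.get("target")
    if mode in ("search", "sweep", "compare") and target is None:
        raise ConfigError(f"experiment mode {mode!r} requires a target")
    sweep = eblock.get("sweep")
    if mode == "sweep":
        if not sweep or "variable" not in sweep or "grid" not in sweep:
            raise ConfigError("sweep mode needs sweep: {variable, grid}")
    compare = list(eblock.get("compare") or [])
    passage = str(eblock.get("passage", "first_passage"))
    if passage not in ("first_passage", "at_horizon"):
        raise ConfigError(f"unknown passage rule {passage!r}")

    return RunConfig(
        spec=spec, lifecycle=lifecycle, release=release, mode=mode,
        horizon=int(eblock.get("horizon", 40)),
        target=None if target is None else float(target),
        passage=passage, sweep=sweep, compare=compare,
        seed=raw.get("seed"),
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" (line {mark.line + 1})" if mark else ""
        raise ConfigError(f"malformed YAML in {path}{line}: {exc}") from exc
    try:
        return parse_config(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def resolved_parameters(config: RunConfig) -> dict:
    """The fully resolved parameter set of a run, for logs and manifests."""
    return {
        "strategy": config.spec.name,
        "options": {k: v for k, v in config.spec.options if v is not None},
        "params": asdict(config.spec.params),
        "release_genotype": config.spec.release_genotype.label(),
        "loci": [
            {"name": l.name, "role": l.role, "alleles": list(l.alleles)}
            for l in config.spec.arch.loci
        ],
        "Rm": config.lifecycle.Rm,
        "dd_exponent": config.lifecycle.dd_exponent,
        "rho": config.release.rho,
        "cadence": config.release.cadence,
        "mode": config.mode,
        "horizon": config.horizon,
        "target": config.target,
        "passage": config.passage,
    }


def write_manifest(outdir, config: RunConfig, outputs: list) -> Path:
    """Write a JSON manifest: config hash, package version, parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package": "drivebalance",
        "version": _version(),
        "config_sha256": digest,
        "outputs": [str(p) for p in outputs],
        "resolved": resolved_parameters(config),
        "seed": config.seed,  # reserved: the engine is deterministic
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


_FIXTURE_EXTRAS = {
    "pdne1": {},
    "pdne2": {},
    "sit": {},
    "ridl": {},
    "fsridl": {},
    "xs": {},
    "yle": {},
    "fsridl_drive": {},
}


def write_fixtures(outdir) -> list:
    """Write one valid example configuration per registered strategy."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in strategy_names():
        cfg = {
            "strategy": {"name": name, "idealized": True,
                         "options": _FIXTURE_EXTRAS.get(name, {})},
            "demography": {"Rm": 6.0, "dd_exponent": 1.0},
            "release": {"rho": 0.1, "cadence": "every", "start": 0,
                        "stop": None},
            "experiment": {"mode": "timeseries", "horizon": 20},
            "seed": None,
            "log_level": "INFO",
        }
        path = outdir / f"{name}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        parse_config(yaml.safe_load(path.read_text()))  # round-trip check
        paths.append(path)
    return paths
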