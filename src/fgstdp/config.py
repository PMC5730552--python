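"""TOML configuration, fixture generation and run manifests.

Configs are flat TOML with one table per component; keys carry the units
practitioners write (mV, ms, fF, nm) and are converted to SI on load.
Unknown keys are rejected so typos fail loudly.  Every CLI run writes a
manifest (resolved config + seed + package version) sufficient to
reproduce its outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .device import default_storage_leak
from .neuron import SteinParams, alternating_trains_with_bins, poisson_train
from .synapse import SynapseParams
from .variability import VariabilityParams

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "load_config",
    "dump_config",
    "make_fixtures",
    "write_manifest",
    "setup_logging",
]

log = logging.getLogger("fgstdp")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a terse format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fgstdp")
    root.handlers[:] = [handler]
    root.setLevel(level)


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved, unit-normalized experiment configuration."""

    synapse: SynapseParams = field(default_factory=SynapseParams)
    neuron: SteinParams = field(default_factory=SteinParams)
    variability: VariabilityParams = field(default_factory=VariabilityParams)
    device_mode: str = "tunneling"
    device_tau_s: float | None = None
    device_t_tun_nm: float = 1.3
    device_c_fg_ff: float = 2.0
    device_barrier_ev: float = 3.1
    device_m_star: float = 0.4
    device_area_nm2: float = 60.0 * 120.0
    protocol: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."


# (config key, params field, scale to SI)
_SYNAPSE_KEYS = {
    "dv_pre_mv": ("dv_pre", 1e-3),
    "dv_post_mv": ("dv_post", 1e-3),
    "tau_pre_ms": ("tau_pre_s", 1e-3),
    "tau_post_ms": ("tau_post_s", 1e-3),
    "gain_pre": ("gain_pre", 1.0),
    "gain_post": ("gain_post", 1.0),
    "theta_post_v": ("theta_post", 1.0),
    "theta_pre_v": ("theta_pre", 1.0),
    "c_plus_v": ("c_plus", 1.0),
    "c_minus_v": ("c_minus", 1.0),
    "lambda_plus_v": ("lambda_plus", 1.0),
    "lambda_minus_v": ("lambda_minus", 1.0),
    "vtc_vmax_v": ("vtc_vmax", 1.0),
    "vtc_slope_v": ("vtc_slope", 1.0),
    "vtc_mid_v": ("vtc_mid", 1.0),
    "m_rest_v": ("m_rest", 1.0),
    "pairing_mode": ("pairing_mode", None),
    "storage_c_ff": ("storage_c_f", 1e-15),
    "storage_leak": None,  # boolean: attach the calibrated storage leak
}
_NEURON_KEYS = {
    "tau_m_ms": ("tau_m_s", 1e-3),
    "threshold_mv": ("threshold_mv", 1.0),
    "alpha": ("alpha", 1.0),
    "reset_mv": ("reset_mv", 1.0),
}
_VARIABILITY_KEYS = {
    "a_rdf": ("a_rdf", 1.0),
    "a_ler": ("a_ler", 1.0),
    "vth_sensitivity_per_mv": ("vth_sensitivity_per_mv", 1.0),
    "m_rest_sensitivity": ("m_rest_sensitivity", 1.0),
}
_DEVICE_KEYS = {"mode", "tau_s", "t_tun_nm", "c_fg_ff", "barrier_ev", "m_star", "area_nm2"}
_TOP_KEYS = {"synapse", "neuron", "variability", "device", "protocol", "seed", "out_dir"}


def _build(section: dict, keymap: dict, factory, what: str):
    kwargs = {}
    for key, value in section.items():
        if key not in keymap:
            raise ConfigError(f"unknown key {key!r} in [{what}]")
        spec = keymap[key]
        if spec is None:
            continue
        name, scale = spec
        if scale is None:
            kwargs[name] = value
        else:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"[{what}] {key} must be a number")
            kwargs[name] = value * scale
    try:
        return factory(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid [{what}] section: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Load, validate and unit-normalize a TOML experiment configuration."""
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    syn_section = dict(raw.get("synapse", {}))
    storage_leak_on = bool(syn_section.pop("storage_leak", False))
    synapse = _build(syn_section, _SYNAPSE_KEYS, SynapseParams, "synapse")
    if storage_leak_on:
        synapse = replace(synapse, storage_leak=default_storage_leak())
    neuron = _build(raw.get("neuron", {}), _NEURON_KEYS, SteinParams, "neuron")
    variability = _build(
        raw.get("variability", {}), _VARIABILITY_KEYS, VariabilityParams, "variability"
    )

    dev = dict(raw.get("device", {}))
    unknown = set(dev) - _DEVICE_KEYS
    if unknown:
        raise ConfigError(f"unknown keys in [device]: {sorted(unknown)}")
    mode = dev.get("mode", "tunneling")
    if mode not in ("tunneling", "exponential"):
        raise ConfigError(f"[device] mode must be tunneling|exponential, got {mode!r}")
    for key in ("tau_s", "t_tun_nm", "c_fg_ff", "barrier_ev", "m_star", "area_nm2"):
        if key in dev and not (isinstance(dev[key], (int, float)) and dev[key] > 0):
            raise ConfigError(f"[device] {key} must be a positive number")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed must be a non-negative integer")

    return ExperimentConfig(
        synapse=synapse,
        neuron=neuron,
        variability=variability,
        device_mode=mode,
        device_tau_s=dev.get("tau_s"),
        device_t_tun_nm=dev.get("t_tun_nm", 1.3),
        device_c_fg_ff=dev.get("c_fg_ff", 2.0),
        device_barrier_ev=dev.get("barrier_ev", 3.1),
        device_m_star=dev.get("m_star", 0.4),
        device_area_nm2=dev.get("area_nm2", 60.0 * 120.0),
        protocol=dict(raw.get("protocol", {})),
        seed=seed,
        out_dir=str(raw.get("out_dir", ".")),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_config(cfg: ExperimentConfig) -> str:
    """Serialize a configuration back to TOML (inverse of load_config)."""
    syn = cfg.synapse
    lines = [f"seed = {cfg.seed}", f'out_dir = {_toml_value(cfg.out_dir)}', ""]
    lines.append("[synapse]")
    for key, spec in _SYNAPSE_KEYS.items():
        if spec is None:
            lines.append(f"storage_leak = {_toml_value(syn.storage_leak is not None)}")
            continue
        name, scale = spec
        value = getattr(syn, name)
        if scale not in (None, 1.0):
            value = value / scale
        lines.append(f"{key} = {_toml_value(value)}")
    lines.append("")
    lines.append("[neuron]")
    for key, (name, scale) in _NEURON_KEYS.items():
        value = getattr(cfg.neuron, name)
        if scale != 1.0:
            value = value / scale
        lines.append(f"{key} = {_toml_value(value)}")
    lines.append("")
    lines.append("[variability]")
    for key, (name, _) in _VARIABILITY_KEYS.items():
        lines.append(f"{key} = {_toml_value(getattr(cfg.variability, name))}")
    lines.append("")
    lines.append("[device]")
    lines.append(f'mode = {_toml_value(cfg.device_mode)}')
    if cfg.device_tau_s is not None:
        lines.append(f"tau_s = {_toml_value(cfg.device_tau_s)}")
    lines.append(f"t_tun_nm = {_toml_value(cfg.device_t_tun_nm)}")
    lines.append(f"c_fg_ff = {_toml_value(cfg.device_c_fg_ff)}")
    lines.append(f"barrier_ev = {_toml_value(cfg.device_barrier_ev)}")
    lines.append(f"m_star = {_toml_value(cfg.device_m_star)}")
    lines.append(f"area_nm2 = {_toml_value(cfg.device_area_nm2)}")
    if cfg.protocol:
        lines.append("")
        lines.append("[protocol]")
        for key, value in sorted(cfg.protocol.items()):
            lines.append(f"{key} = {_toml_value(value)}")
    return "\n".join(lines) + "\n"


def _write_train_csv(path: Path, trains) -> None:
    with path.open("w", newline="") as fh:
        fh.write("time_s,source_id\n")
        rows = []
        for tr in trains:
            rows.extend((t, tr.source_id) for t in tr.times)
        rows.sort()
        for t, sid in rows:
            fh.write(f"{t:.9f},{sid}\n")


def write_manifest(out_dir: Path, seed: int, parameters: dict, files: list[Path]) -> Path:
    """Record seed, parameters and output checksums for reproducibility."""
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
        "checksums": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def make_fixtures(kind: str, seed: int, out_dir) -> list[Path]:
    """Write deterministic spike-train fixtures plus a manifest.

    Kinds: ``pairing`` (1 ms offset pairs at 20 Hz for 10 s), ``poisson``
    (two 5 Hz trains, 100 s), ``alternating`` and ``supervised``
    (200 ms bins at 20 Hz, 100 s).  Regeneration under the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    from .neuron import SpikeTrain  # local import to avoid cycle at module load

    if kind == "pairing":
        t1 = np.arange(0.0, 10.0, 0.050)
        t2 = t1 + 0.001
        trains = [SpikeTrain(times=t1, source_id="N1"),
                  SpikeTrain(times=t2, source_id="N2")]
        params = {"kind": kind, "dt_pair_ms": 1.0, "period_ms": 50.0, "duration_s": 10.0}
    elif kind == "poisson":
        seeds = ss.spawn(2)
        trains = [poisson_train(5.0, 100.0, seeds[i], source_id=f"N{i+1}") for i in range(2)]
        params = {"kind": kind, "rate_hz": 5.0, "duration_s": 100.0}
    elif kind in ("alternating", "supervised"):
        bins_ss, sup_ss = ss.spawn(2)
        trains, active = alternating_trains_with_bins(20.0, 0.2, 100.0, 2, bins_ss)
        params = {"kind": kind, "rate_hz": 20.0, "bin_ms": 200.0, "duration_s": 100.0}
        if kind == "supervised":
            extra = poisson_train(60.0, 100.0, sup_ss).times
            if extra.size:
                b = np.minimum((extra / 0.2).astype(int), active.size - 1)
                extra = extra[active[b] == 0]
            sup = np.unique(np.concatenate([trains[0].times + 0.001, extra]))
            trains = list(trains) + [SpikeTrain(times=sup[sup < 100.0], source_id="Nsup")]
            params["sup_rate_hz"] = 80.0
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    csv_path = out_dir / f"{kind}_spikes.csv"
    _write_train_csv(csv_path, trains)
    manifest = write_manifest(out_dir, seed, params, [csv_path])
    return [csv_path, manifest]
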