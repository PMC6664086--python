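"""Run configuration, presets and network assembly.

Configurations are flat, human-editable key-value documents with dotted keys
and explicit units in key names (``run.duration_ms``, ``kernel.imd_mm``,
``efficacy.nu_ext_hz`` ...).  ``validate_config`` turns such a document into
a typed :class:`RunConfig`, reporting every violated constraint at once.
Presets bundle the calibrated parameter tables for the slow-wave (SW) and
asynchronous (AW) regimes at two module scales: the full 1,250-neuron module
and a reduced 150-neuron module whose efficacies were re-calibrated with the
mean-field planner for desk-scale spiking runs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .network import (
    ConnectivityKernel,
    EfficacyMatrix,
    GridSpec,
    SynapseTable,
    assign_delays,
    assign_weights,
    make_grid_spec,
    sample_synapses,
)
from .neuron import NeuronParams
from .engine import Network

__all__ = [
    "RunConfig",
    "ConfigValidationError",
    "preset",
    "preset_names",
    "validate_config",
    "build_network",
]


class ConfigValidationError(ValueError):
    """One or more configuration keys violate their constraints."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  " + "\n  ".join(violations))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-exactly (plus the seed)."""

    grid: GridSpec
    kernel: ConnectivityKernel
    eff: EfficacyMatrix
    params: dict  # population -> NeuronParams
    delays_policy: str = "uniform"
    delays_value_ms: int = 1
    delays_v_axon_mm_per_ms: float | None = None
    regime: str | None = None
    duration_ms: float = 1000.0
    comm_step_ms: float = 1.0
    seed: int = 0
    partitions: int = 1
    init: str = "spread"
    bin_ms: float = 5.0
    logmua_noise_var: float = 0.5
    tau_E_ms: float = 10.0
    tau_I_ms: float = 5.0
    out_dir: str = "."

    def to_document(self) -> dict:
        """Flat dotted-key representation (round-trips through validate_config)."""
        doc = {
            "grid.rows": self.grid.rows,
            "grid.cols": self.grid.cols,
            "module.KF": self.grid.K_F,
            "module.KB": self.grid.K_B,
            "module.KI": self.grid.K_I,
            "kernel.lambda_imd": self.kernel.lambda_imd,
            "kernel.in_degree_fraction": self.kernel.in_degree_fraction,
            "kernel.imd_mm": self.grid.imd_mm,
            "efficacy.J": [[float(x) for x in r] for r in self.eff.J_array],
            "efficacy.cv": self.eff.cv,
            "efficacy.J_ext_mv": self.eff.J_ext,
            "efficacy.delta_J_ext_mv": self.eff.delta_J_ext,
            "efficacy.nu_ext_hz": ([float(x) for x in self.eff.nu_ext_hz]
                                   if np.ndim(self.eff.nu_ext_hz)
                                   else float(self.eff.nu_ext_hz)),
            "delays.policy": self.delays_policy,
            "delays.value_ms": self.delays_value_ms,
            "run.duration_ms": self.duration_ms,
            "run.comm_step_ms": self.comm_step_ms,
            "run.seed": self.seed,
            "run.partitions": self.partitions,
            "run.init": self.init,
            "analysis.bin_ms": self.bin_ms,
            "analysis.logmua_noise_var": self.logmua_noise_var,
            "meanfield.tau_E_ms": self.tau_E_ms,
            "meanfield.tau_I_ms": self.tau_I_ms,
            "out_dir": self.out_dir,
        }
        if self.delays_v_axon_mm_per_ms is not None:
            doc["delays.v_axon_mm_per_ms"] = self.delays_v_axon_mm_per_ms
        if self.regime is not None:
            doc["regime"] = self.regime
        for p, np_ in self.params.items():
            for k, v in np_.to_dict().items():
                doc[f"neuron.{p}.{k}"] = v
        return doc

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_document(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# calibrated parameter tables

def _exc_params(g_c: float, tau_c: float, alpha_c: float = 1.0) -> NeuronParams:
    return NeuronParams(tau_m=20.0, C_m=1.0, E=0.0, V_theta=20.0, V_r=5.0,
                        tau_arp=2.0, g_c=g_c, alpha_c=alpha_c, tau_c=tau_c)


def _inh_params() -> NeuronParams:
    return NeuronParams(tau_m=10.0, C_m=1.0, E=0.0, V_theta=20.0, V_r=5.0,
                        tau_arp=1.0, g_c=0.0, tau_c=150.0, inhibitory=True)


# Efficacy tables (mV jump magnitudes, J[target][source], populations F,B,I;
# external Poisson rates per population).  Calibrated with the mean-field
# planner plus spiking-network refinement (see docs/methods.md): the AW
# tables sit at a single stable fixed point whose population-average rate is
# 8.8 Hz; the SW tables combine a quiet, weakly stable Down state with a
# recruited-inhibition Up branch and strong adaptation, producing the
# fatigue-paced Up/Down alternation around 3 Hz.  The two states also differ
# in adaptation strength (g_c, tau_c): spike-frequency adaptation is strong
# in the sleep-like state and reduced in the wake-like state, mimicking its
# neuromodulatory suppression in wakefulness.

_MINI = dict(  # 150-neuron module, in-degree 27/81/27; spiking-validated
    J_SW=((1.6000, 0.0500, 2.5000),
          (0.7000, 0.1000, 0.5000),
          (2.0000, 0.1000, 0.3000)),
    nu_ext_SW=(1480.0, 1400.0, 1200.0),
    g_c_SW=0.08, tau_c_SW=650.0,
    J_AW=((0.3000, 0.1000, 1.2000),
          (0.15416, 0.1000, 0.27925),
          (0.2790, 0.46953, 0.8000)),
    nu_ext_AW=(2507.1, 1600.0, 2900.0),
    g_c_AW=0.06, tau_c_AW=150.0,
    J_ext=0.5, dJ_ext=0.12,
)

# 1,250-neuron module, in-degree 225/675/225: the mini tables scaled by the
# in-degree ratio 27/225 (same mean input), with the F-to-F entry of the SW
# table re-tuned by the mean-field planner to restore the oscillation.
_S = 27.0 / 225.0
_FULL = dict(
    J_SW=((1.6 * _S * 1.8, 0.05 * _S, 2.5 * _S),
          (0.7 * _S, 0.1 * _S, 0.5 * _S),
          (2.0 * _S, 0.1 * _S, 0.3 * _S)),
    nu_ext_SW=(1350.0, 1400.0, 1200.0),
    g_c_SW=0.08, tau_c_SW=650.0,
    J_AW=((0.3 * _S, 0.1 * _S, 1.2 * _S),
          (0.15416 * _S, 0.1 * _S, 0.27925 * _S),
          (0.279 * _S, 0.46953 * _S, 0.8 * _S)),
    nu_ext_AW=(2507.1, 1600.0, 2900.0),
    g_c_AW=0.06, tau_c_AW=150.0,
    J_ext=0.5, dJ_ext=0.12,
)


def _make_config(rows, cols, KF, KB, KI, lam, table, regime, duration) -> RunConfig:
    J = table[f"J_{regime}"]
    nu_ext = table[f"nu_ext_{regime}"]
    eff = EfficacyMatrix(J=J, cv=0.25, J_ext=table["J_ext"],
                         delta_J_ext=table["dJ_ext"], nu_ext_hz=nu_ext)
    exc = _exc_params(table[f"g_c_{regime}"], table[f"tau_c_{regime}"])
    params = {"F": exc, "B": exc, "I": _inh_params()}
    return RunConfig(
        grid=GridSpec(rows=rows, cols=cols, K_F=KF, K_B=KB, K_I=KI, imd_mm=0.4),
        kernel=ConnectivityKernel(lambda_imd=lam, in_degree_fraction=0.9),
        eff=eff,
        params=params,
        regime=regime,
        duration_ms=duration,
    )


_PRESETS = {
    # full-size modules (mean-field checked; spiking runs are heavy)
    "SW-default": lambda: _make_config(24, 24, 250, 750, 250, 0.4, _FULL, "SW", 10000.0),
    "AW-default": lambda: _make_config(24, 24, 250, 750, 250, 0.4, _FULL, "AW", 10000.0),
    # 12x12 test fixtures at full module size
    "toy-SW": lambda: _make_config(12, 12, 250, 750, 250, 0.4, _FULL, "SW", 5000.0),
    "toy-AW": lambda: _make_config(12, 12, 250, 750, 250, 0.4, _FULL, "AW", 5000.0),
    # reduced 150-neuron modules for desk-scale spiking runs
    "mini-SW": lambda: _make_config(12, 12, 30, 90, 30, 0.6, _MINI, "SW", 8000.0),
    "mini-AW": lambda: _make_config(12, 12, 30, 90, 30, 0.6, _MINI, "AW", 5000.0),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> RunConfig:
    """Return a named, validated run configuration."""
    if name not in _PRESETS:
        raise ConfigValidationError([f"unknown preset {name!r}; "
                                     f"known: {', '.join(preset_names())}"])
    return _PRESETS[name]()


# --------------------------------------------------------------------------
# validation

def validate_config(raw: dict) -> RunConfig:
    """Turn a flat dotted-key document into a typed, range-checked RunConfig.

    Unknown keys, type errors and violated invariants are all collected and
    reported together, each naming the offending key.
    """
    doc = dict(raw)
    errors: list[str] = []
    base = None
    if "preset" in doc:
        try:
            base = preset(str(doc.pop("preset")))
        except ConfigValidationError as e:
            raise ConfigValidationError(e.violations)
    if base is None:
        base = preset("mini-AW")
    merged = base.to_document()
    for k, v in doc.items():
        if k not in merged and not k.startswith("neuron."):
            errors.append(f"unknown key {k}")
        merged[k] = v

    def get(key, typ, check=None, msg=""):
        try:
            v = typ(merged[key])
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot convert {merged[key]!r}")
            return None
        if check is not None and not check(v):
            errors.append(f"{key}: {msg} (got {v!r})")
            return None
        return v

    rows = get("grid.rows", int, lambda v: v >= 1, "must be >= 1")
    cols = get("grid.cols", int, lambda v: v >= 1, "must be >= 1")
    KF = get("module.KF", int, lambda v: v >= 0, "must be >= 0")
    KB = get("module.KB", int, lambda v: v >= 0, "must be >= 0")
    KI = get("module.KI", int, lambda v: v >= 0, "must be >= 0")
    lam = get("kernel.lambda_imd", float, lambda v: v > 0, "must be > 0")
    frac = get("kernel.in_degree_fraction", float, lambda v: 0 < v <= 1,
               "must be in (0, 1]")
    imd = get("kernel.imd_mm", float, lambda v: v > 0, "must be > 0")
    nu_raw = merged["efficacy.nu_ext_hz"]
    try:
        nu_ext = (tuple(float(x) for x in nu_raw) if np.ndim(nu_raw)
                  else float(nu_raw))
        if np.any(np.asarray(nu_ext) < 0):
            errors.append("efficacy.nu_ext_hz: must be >= 0")
        elif np.ndim(nu_ext) and len(nu_ext) != 3:
            errors.append("efficacy.nu_ext_hz: scalar or per-population triple")
    except (TypeError, ValueError):
        errors.append(f"efficacy.nu_ext_hz: cannot convert {nu_raw!r}")
        nu_ext = 0.0
    cv = get("efficacy.cv", float, lambda v: v >= 0, "must be >= 0")
    duration = get("run.duration_ms", float, lambda v: v > 0, "must be > 0")
    comm = get("run.comm_step_ms", float, lambda v: v > 0, "must be > 0")
    seed = get("run.seed", int)
    parts = get("run.partitions", int, lambda v: v >= 1, "must be >= 1")
    bin_ms = get("analysis.bin_ms", float, lambda v: v > 0, "must be > 0")
    nvar = get("analysis.logmua_noise_var", float, lambda v: v >= 0, "must be >= 0")
    policy = get("delays.policy", str, lambda v: v in ("uniform", "distance"),
                 "must be 'uniform' or 'distance'")
    dval = get("delays.value_ms", int, lambda v: v >= 1, "must be >= 1 ms")
    if policy == "uniform" and comm is not None and dval is not None and comm > dval:
        errors.append("run.comm_step_ms: exceeds minimum delay delays.value_ms "
                      f"({comm} > {dval}): causality violated")
    v_axon = merged.get("delays.v_axon_mm_per_ms")
    if policy == "distance" and (v_axon is None or float(v_axon) <= 0):
        errors.append("delays.v_axon_mm_per_ms: required and > 0 for the "
                      "distance policy")
    try:
        J = tuple(tuple(float(x) for x in row) for row in merged["efficacy.J"])
        if len(J) != 3 or any(len(r) != 3 for r in J):
            errors.append("efficacy.J: must be a 3x3 matrix")
        elif any(x < 0 for r in J for x in r):
            errors.append("efficacy.J: entries are magnitudes, must be >= 0")
    except (TypeError, ValueError):
        errors.append("efficacy.J: must be a 3x3 numeric matrix")
        J = None
    params = {}
    for p in ("F", "B", "I"):
        d = {k.split(".")[-1]: v for k, v in merged.items()
             if k.startswith(f"neuron.{p}.")}
        try:
            params[p] = NeuronParams.from_dict(d)
        except (TypeError, ValueError) as e:
            errors.append(f"neuron.{p}: {e}")
    if errors:
        raise ConfigValidationError(errors)
    return RunConfig(
        grid=GridSpec(rows=rows, cols=cols, K_F=KF, K_B=KB, K_I=KI, imd_mm=imd),
        kernel=ConnectivityKernel(lambda_imd=lam, in_degree_fraction=frac),
        eff=EfficacyMatrix(J=J, cv=cv, J_ext=float(merged["efficacy.J_ext_mv"]),
                           delta_J_ext=float(merged["efficacy.delta_J_ext_mv"]),
                           nu_ext_hz=nu_ext),
        params=params,
        delays_policy=policy,
        delays_value_ms=dval,
        delays_v_axon_mm_per_ms=None if v_axon is None else float(v_axon),
        regime=merged.get("regime"),
        duration_ms=duration,
        comm_step_ms=comm,
        seed=seed,
        partitions=parts,
        init=str(merged["run.init"]),
        bin_ms=bin_ms,
        logmua_noise_var=nvar,
        tau_E_ms=float(merged["meanfield.tau_E_ms"]),
        tau_I_ms=float(merged["meanfield.tau_I_ms"]),
        out_dir=str(merged["out_dir"]),
    )


# --------------------------------------------------------------------------
# assembly

def build_network(config: RunConfig, seed: int | None = None) -> Network:
    """Sample the connectome and assemble a runnable Network."""
    seed = config.seed if seed is None else seed
    table = sample_synapses(config.grid, config.kernel, seed=seed)
    table = assign_weights(table, config.eff, seed=seed)
    table = assign_delays(table, policy=config.delays_policy,
                          value_ms=config.delays_value_ms,
                          v_axon_mm_per_ms=config.delays_v_axon_mm_per_ms)
    return Network(spec=config.grid, table=table, eff=config.eff,
                   params=config.params)
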