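"""Modular grid construction and distance-dependent connectivity.

The network is a 2D grid of cortical modules ("columns"), each composed of
three subpopulations: foreground excitatory (F), background excitatory (B)
and inhibitory (I).  Excitatory neurons project across the grid with a
connection probability that decays exponentially with the Euclidean
inter-module distance, ``p(d) ~ exp(-d / lambda)``; inhibitory projections
are strictly local to the source module.  The per-target expected in-degree
from every source population is held fixed (``M_s = f * K_s``) for all decay
constants, so the total synapse count is independent of the connectivity
range.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "POPULATIONS",
    "GridSpec",
    "ConnectivityKernel",
    "EfficacyMatrix",
    "SynapseTable",
    "make_grid_spec",
    "kernel_column_weights",
    "sample_synapses",
    "assign_weights",
    "assign_delays",
]

#: Subpopulation order used everywhere: foreground, background, inhibitory.
POPULATIONS = ("F", "B", "I")

#: Packed on-disk synapse record: 4 + 4 + 2 + 1 + 1 = 12 bytes.
SYNAPSE_RECORD_DTYPE = np.dtype(
    [
        ("source", "<u4"),
        ("target", "<u4"),
        ("weight", "<i2"),
        ("delay", "u1"),
        ("kind", "u1"),
    ]
)


class ConfigurationError(ValueError):
    """Invalid network/kernel configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and composition of the module grid.

    Neurons are numbered globally: ``gid = module_index * K + local index``
    with ``module_index = row * cols + col`` (row-major).  Within a module,
    local indices ``[0, K_F)`` are F, ``[K_F, K_F+K_B)`` are B and the rest
    are I.
    """

    rows: int
    cols: int
    K_F: int = 250
    K_B: int = 750
    K_I: int = 250
    imd_mm: float = 0.4

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if min(self.K_F, self.K_B, self.K_I) < 0:
            raise ConfigurationError("population sizes must be >= 0")
        if self.imd_mm <= 0:
            raise ConfigurationError("imd_mm must be positive")

    @property
    def K(self) -> int:
        return self.K_F + self.K_B + self.K_I

    @property
    def n_modules(self) -> int:
        return self.rows * self.cols

    @property
    def n_neurons(self) -> int:
        return self.n_modules * self.K

    def pop_sizes(self) -> tuple[int, int, int]:
        return (self.K_F, self.K_B, self.K_I)

    def pop_offset(self, pop: str) -> int:
        """Local index of the first neuron of ``pop`` within a module."""
        return {"F": 0, "B": self.K_F, "I": self.K_F + self.K_B}[pop]

    def module_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ConfigurationError("module outside the grid")
        return row * self.cols + col

    def module_rc(self, module: int | np.ndarray):
        return np.divmod(module, self.cols)

    def neuron_module(self, gid):
        return np.asarray(gid) // self.K

    def neuron_population(self, gid) -> np.ndarray:
        """Population code per neuron: 0 = F, 1 = B, 2 = I."""
        local = np.asarray(gid) % self.K
        return np.where(local < self.K_F, 0, np.where(local < self.K_F + self.K_B, 1, 2))

    def is_excitatory(self, gid) -> np.ndarray:
        return self.neuron_population(gid) < 2

    def module_distances(self, target_module: int) -> np.ndarray:
        """Euclidean distance (imd units) from every module to ``target_module``."""
        r0, c0 = self.module_rc(target_module)
        rr, cc = self.module_rc(np.arange(self.n_modules))
        return np.hypot(rr - r0, cc - c0)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "K_F": self.K_F,
            "K_B": self.K_B,
            "K_I": self.K_I,
            "imd_mm": self.imd_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def make_grid_spec(rows: int, cols: int, module_template: dict | None = None) -> GridSpec:
    """Build a :class:`GridSpec` from grid dimensions and a module template.

    ``module_template`` may supply ``K_F``, ``K_B``, ``K_I`` and ``imd_mm``;
    missing keys use the defaults (250 / 750 / 250 neurons, 0.4 mm).
    """
    template = dict(module_template or {})
    return GridSpec(rows=rows, cols=cols, **template)


@dataclass(frozen=True)
class ConnectivityKernel:
    """Exponential spatial connectivity kernel.

    ``lambda_imd`` is the decay constant of the connection probability in
    inter-module-distance units.  ``in_degree_fraction`` fixes the expected
    in-degree from each source population at ``M_s = in_degree_fraction * K_s``,
    independently of ``lambda_imd`` (the per-target normalization constant
    absorbs the kernel mass actually present inside the open-boundary grid).
    """

    lambda_imd: float = 0.4
    in_degree_fraction: float = 0.9

    def __post_init__(self):
        if self.lambda_imd <= 0:
            raise ConfigurationError("lambda_imd must be > 0")
        if not (0 < self.in_degree_fraction <= 1):
            raise ConfigurationError("in_degree_fraction must be in (0, 1]")

    def in_degree(self, K_s: int) -> int:
        return int(round(self.in_degree_fraction * K_s))


def kernel_column_weights(
    spec: GridSpec,
    kernel: ConnectivityKernel,
    target_module: int,
    source_kind: str = "excitatory",
) -> np.ndarray:
    """Normalized probability of drawing each source module for one target.

    For excitatory sources the weight of the module at distance ``d`` is
    proportional to ``exp(-d / lambda)``, renormalized to sum to one over the
    modules actually present in the grid (open boundaries).  For inhibitory
    sources all weight sits on the target's own module.
    """
    if not (0 <= target_module < spec.n_modules):
        raise ConfigurationError("target module outside the grid")
    w = np.zeros(spec.n_modules)
    if source_kind == "inhibitory":
        w[target_module] = 1.0
        return w
    if source_kind != "excitatory":
        raise ConfigurationError(f"unknown source kind {source_kind!r}")
    d = spec.module_distances(target_module)
    # subtract the minimum (0) before exponentiating: harmless, but keeps the
    # normalization well-conditioned for very small lambda
    w = np.exp(-d / kernel.lambda_imd)
    return w / w.sum()


@dataclass(frozen=True)
class EfficacyMatrix:
    """Mean synaptic efficacies J_ts (mV jump per spike) and their spread.

    ``J[t][s]`` is the mean magnitude of the membrane-potential jump for a
    synapse from source population ``s`` onto target population ``t``
    (populations ordered F, B, I).  Individual weights are Gaussian with
    standard deviation ``cv * J_ts`` (coefficient of variation 0.25 by
    default); the sign is set by the source kind (+ for F/B, - for I).
    External Poisson input is described by ``J_ext``/``delta_J_ext`` (mV) and
    the total rate ``nu_ext_hz`` seen by one neuron.
    """

    J: tuple  # 3x3 nested tuple of mean magnitudes, J[t][s]
    cv: float = 0.25
    J_ext: float = 0.4
    delta_J_ext: float = 0.1
    nu_ext_hz: float | tuple = 1000.0  # scalar, or per-population (F, B, I)

    def __post_init__(self):
        arr = np.asarray(self.J, dtype=float)
        if arr.shape != (3, 3):
            raise ConfigurationError("J must be a 3x3 (target, source) matrix")
        if np.any(arr < 0):
            raise ConfigurationError("J entries are magnitudes and must be >= 0")
        if np.any(np.asarray(self.nu_ext_hz) < 0):
            raise ConfigurationError("nu_ext_hz must be >= 0")

    def nu_ext_per_pop(self) -> np.ndarray:
        """External Poisson rate seen by one neuron of each population (Hz)."""
        v = np.asarray(self.nu_ext_hz, dtype=float)
        if v.ndim == 0:
            return np.full(3, float(v))
        if v.shape != (3,):
            raise ConfigurationError("nu_ext_hz must be scalar or length-3")
        return v

    @property
    def J_array(self) -> np.ndarray:
        return np.asarray(self.J, dtype=float)

    def delta_J_array(self) -> np.ndarray:
        return self.cv * self.J_array

    def scaled(self, pair_factors: dict[tuple[str, str], float]) -> "EfficacyMatrix":
        """Return a copy with selected (target, source) entries multiplied."""
        arr = self.J_array.copy()
        for (t, s), f in pair_factors.items():
            arr[POPULATIONS.index(t), POPULATIONS.index(s)] *= f
        return replace(self, J=tuple(map(tuple, arr)))

    def to_dict(self) -> dict:
        nu = self.nu_ext_hz
        return {
            "J": [list(row) for row in self.J_array],
            "cv": self.cv,
            "J_ext": self.J_ext,
            "delta_J_ext": self.delta_J_ext,
            "nu_ext_hz": list(nu) if np.ndim(nu) else float(nu),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EfficacyMatrix":
        d = dict(d)
        d["J"] = tuple(map(tuple, d["J"]))
        if np.ndim(d.get("nu_ext_hz", 0.0)):
            d["nu_ext_hz"] = tuple(d["nu_ext_hz"])
        return cls(**d)


def kind_code(target_pop: int, source_pop: int) -> int:
    """Synapse kind tag enumerating the (target, source) population pair."""
    return target_pop * 3 + source_pop


@dataclass
class SynapseTable:
    """The static recurrent connectome as parallel arrays.

    ``weight`` holds the signed membrane-potential jump in mV (full double
    precision in memory); serialization quantizes it to a 2-byte fixed-point
    field with a per-kind scale, giving the packed 12-byte record
    (uint32 source, uint32 target, int16 weight, uint8 delay, uint8 kind).
    """

    spec: GridSpec
    source: np.ndarray  # uint32 global ids
    target: np.ndarray  # uint32 global ids
    weight: np.ndarray  # float64 signed mV
    delay_ms: np.ndarray  # uint8, >= 1
    kind: np.ndarray  # uint8 (target_pop * 3 + source_pop)

    @property
    def n_synapses(self) -> int:
        return self.source.size

    def out_degree(self) -> np.ndarray:
        return np.bincount(self.source, minlength=self.spec.n_neurons)

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.target, minlength=self.spec.n_neurons)

    # --- 12-byte packed serialization -------------------------------------

    def _weight_scales(self) -> np.ndarray:
        """Fixed-point scale per kind so the largest magnitude fits int16."""
        scales = np.ones(9)
        for k in range(9):
            m = self.kind == k
            if m.any():
                wmax = np.abs(self.weight[m]).max()
                scales[k] = 32000.0 / wmax if wmax > 0 else 1.0
        return scales

    def to_records(self) -> tuple[np.ndarray, np.ndarray]:
        """Quantize to the packed record array; returns (records, scales)."""
        scales = self._weight_scales()
        rec = np.empty(self.n_synapses, dtype=SYNAPSE_RECORD_DTYPE)
        rec["source"] = self.source
        rec["target"] = self.target
        rec["weight"] = np.round(self.weight * scales[self.kind]).astype(np.int16)
        rec["delay"] = self.delay_ms
        rec["kind"] = self.kind
        return rec, scales

    def save(self, path: str | Path) -> None:
        """Write packed records plus a JSON sidecar with scales and GridSpec."""
        path = Path(path)
        rec, scales = self.to_records()
        rec.tofile(path)
        sidecar = {
            "grid": self.spec.to_dict(),
            "weight_scales": scales.tolist(),
            "n_synapses": int(self.n_synapses),
            "record_bytes": int(SYNAPSE_RECORD_DTYPE.itemsize),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SynapseTable":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        rec = np.fromfile(path, dtype=SYNAPSE_RECORD_DTYPE)
        scales = np.asarray(sidecar["weight_scales"])
        return cls(
            spec=GridSpec.from_dict(sidecar["grid"]),
            source=rec["source"].astype(np.uint32),
            target=rec["target"].astype(np.uint32),
            weight=rec["weight"].astype(np.float64) / scales[rec["kind"]],
            delay_ms=rec["delay"].astype(np.uint8),
            kind=rec["kind"].astype(np.uint8),
        )

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in (self.source, self.target, self.weight, self.delay_ms, self.kind):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]


def sample_synapses(
    spec: GridSpec,
    kernel: ConnectivityKernel,
    seed: int,
    allow_autapses: bool = False,
) -> SynapseTable:
    """Draw the recurrent connectome with fixed per-target in-degrees.

    Every target neuron receives exactly ``M_s = round(f * K_s)`` synapses
    from each source population ``s``: the source module is drawn from the
    normalized spatial kernel (:func:`kernel_column_weights`; the target's own
    module for inhibitory sources), the source neuron uniformly within that
    module's population.  Multapses are allowed, autapses are resampled away.
    The total synapse count is therefore identical for every ``lambda_imd``.
    """
    rng = np.random.default_rng([int(seed), 0x5EED])
    K = spec.K
    sizes = spec.pop_sizes()
    sources, targets, kinds = [], [], []
    module_targets = np.arange(K, dtype=np.uint32)
    for tm in range(spec.n_modules):
        tgt_gids = (tm * K + module_targets).astype(np.uint32)
        w_exc = kernel_column_weights(spec, kernel, tm, "excitatory")
        for s_pop, s_name in enumerate(POPULATIONS):
            K_s = sizes[s_pop]
            M_s = kernel.in_degree(K_s)
            if M_s == 0:
                continue
            if K_s == 0:
                raise ConfigurationError(
                    f"source population {s_name} empty but M={M_s} requested"
                )
            n_draw = K * M_s
            if s_pop == 2:  # inhibitory: local only
                src_mod = np.full(n_draw, tm, dtype=np.int64)
            else:
                src_mod = rng.choice(spec.n_modules, size=n_draw, p=w_exc)
            src_local = rng.integers(0, K_s, size=n_draw)
            src = (src_mod * K + spec.pop_offset(s_name) + src_local).astype(np.uint32)
            tgt = np.repeat(tgt_gids, M_s)
            if not allow_autapses:
                bad = src == tgt
                while bad.any():
                    src_local = rng.integers(0, K_s, size=int(bad.sum()))
                    src[bad] = (
                        src_mod[bad] * K + spec.pop_offset(s_name) + src_local
                    ).astype(np.uint32)
                    bad = src == tgt
            sources.append(src)
            targets.append(tgt)
            t_pop = spec.neuron_population(tgt)
            kinds.append((t_pop * 3 + s_pop).astype(np.uint8))
    source = np.concatenate(sources)
    target = np.concatenate(targets)
    kind = np.concatenate(kinds)
    return SynapseTable(
        spec=spec,
        source=source,
        target=target,
        weight=np.zeros(source.size),
        delay_ms=np.ones(source.size, dtype=np.uint8),
        kind=kind,
    )


def assign_weights(table: SynapseTable, eff: EfficacyMatrix, seed: int) -> SynapseTable:
    """Draw Gaussian synaptic weights with the source-sign convention.

    Magnitudes are |N(J_ts, cv*J_ts)| (the reflection only matters in the
    ~4-sigma tail and keeps excitatory weights strictly positive); the stored
    sign is + for excitatory sources and - for inhibitory sources.
    """
    rng = np.random.default_rng([int(seed), 0x3E16])
    J = eff.J_array
    dJ = eff.delta_J_array()
    t_pop, s_pop = np.divmod(table.kind, 3)
    mean = J[t_pop, s_pop]
    sd = dJ[t_pop, s_pop]
    mag = np.abs(rng.normal(mean, sd))
    sign = np.where(s_pop == 2, -1.0, 1.0)
    table.weight = sign * mag
    return table


def assign_delays(
    table: SynapseTable,
    policy: str = "uniform",
    value_ms: int = 1,
    v_axon_mm_per_ms: float | None = None,
) -> SynapseTable:
    """Assign integer transmission delays (ms).

    ``uniform``: every synapse gets ``value_ms``.  ``distance``: delay is
    ``max(1, round(d_imd * imd_mm / v_axon_mm_per_ms))`` using the Euclidean
    module distance of each synapse.  All delays are >= 1 ms (the minimum
    delay equals the communication step).
    """
    if policy == "uniform":
        if int(value_ms) < 1:
            raise ConfigurationError("uniform delay must be >= 1 ms")
        table.delay_ms = np.full(table.n_synapses, int(value_ms), dtype=np.uint8)
        return table
    if policy == "distance":
        if v_axon_mm_per_ms is None or v_axon_mm_per_ms <= 0:
            raise ConfigurationError("distance policy needs v_axon_mm_per_ms > 0")
        spec = table.spec
        sm = table.source.astype(np.int64) // spec.K
        tm = table.target.astype(np.int64) // spec.K
        sr, sc = spec.module_rc(sm)
        tr, tc = spec.module_rc(tm)
        d_imd = np.hypot(sr - tr, sc - tc)
        delay = np.maximum(1, np.round(d_imd * spec.imd_mm / v_axon_mm_per_ms))
        if delay.max() > 255:
            raise ConfigurationError("distance policy yields delay > 255 ms")
        table.delay_ms = delay.astype(np.uint8)
        return table
    raise ConfigurationError(f"unknown delay policy {policy!r}")
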