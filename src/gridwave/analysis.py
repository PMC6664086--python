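"""Activity analysis: binned rates, spectra, logMUA, transitions, wave speed.

The chain mirrors how slow-wave experiments are analysed: population rates
binned at 5 ms; Welch power spectra; a multi-unit-activity (MUA) proxy per
module (the module-average firing rate) turned into a log-ratio against its
Down-state baseline with additive noise emulating background fluctuations;
Down-to-Up transition times detected by threshold crossing per module and
clustered into discrete waves; and the wavefront speed field

    V(x, y) = 1 / sqrt((dT/dx)^2 + (dT/dy)^2)

from the spatial gradient of the transition-time map T(x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .engine import SpikeRecord
from .network import GridSpec, POPULATIONS

__all__ = [
    "RateSeries",
    "MUAGrid",
    "WavefrontMap",
    "SpeedStats",
    "bin_rates",
    "welch_psd",
    "compute_mua",
    "log_mua",
    "detect_transitions",
    "wavefront_speed",
    "speed_imd_to_mm_per_s",
]


@dataclass
class RateSeries:
    """Binned firing rates (Hz) per group; counts kept for exact conservation."""

    edges_ms: np.ndarray  # n_bins + 1
    counts: np.ndarray  # (n_bins, n_groups) spike counts
    group_sizes: np.ndarray  # neurons per group
    group_labels: list
    bin_ms: float

    @property
    def rates_hz(self) -> np.ndarray:
        return self.counts / (self.group_sizes[None, :] * self.bin_ms * 1e-3)

    @property
    def centers_ms(self) -> np.ndarray:
        return 0.5 * (self.edges_ms[:-1] + self.edges_ms[1:])

    def total_spikes(self) -> int:
        return int(self.counts.sum())


def _group_of(record: SpikeRecord, spec: GridSpec, grouping: str):
    """Group index per spike plus sizes/labels for the requested grouping."""
    if grouping == "network":
        return (np.zeros(record.n_spikes, np.int64),
                np.array([spec.n_neurons]), ["network"])
    pop = spec.neuron_population(record.neuron)
    mod = spec.neuron_module(record.neuron)
    if grouping == "pop":
        sizes = np.array([k * spec.n_modules for k in spec.pop_sizes()])
        return pop, sizes, list(POPULATIONS)
    if grouping == "module":
        sizes = np.full(spec.n_modules, spec.K)
        return mod, sizes, [f"module_{m}" for m in range(spec.n_modules)]
    if grouping == "module_pop":
        sizes = np.tile(spec.pop_sizes(), spec.n_modules).astype(np.int64)
        labels = [f"module_{m}_{p}" for m in range(spec.n_modules) for p in POPULATIONS]
        return mod * 3 + pop, sizes, labels
    raise ValueError(f"unknown grouping {grouping!r}")


def bin_rates(record: SpikeRecord, spec: GridSpec, bin_ms: float = 5.0,
              grouping: str = "network") -> RateSeries:
    """Bin spikes into per-group firing rates (Hz).

    The rate of a group in a bin is ``count / (group_size * bin)``; summing
    ``rate * bin * group_size`` over everything recovers the spike count
    exactly (counts are stored unrounded).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    group, sizes, labels = _group_of(record, spec, grouping)
    if len(labels) == 0:
        raise ValueError("empty grouping")
    n_bins = int(math.ceil(record.duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    b = np.minimum((record.time_ms // bin_ms).astype(np.int64), n_bins - 1)
    counts = np.zeros((n_bins, len(labels)), dtype=np.int64)
    np.add.at(counts, (b, group), 1)
    return RateSeries(edges_ms=edges, counts=counts, group_sizes=np.asarray(sizes),
                      group_labels=labels, bin_ms=float(bin_ms))


def welch_psd(x: np.ndarray, fs_hz: float, nperseg: int | None = None,
              window: str = "hann", noverlap: int | None = None,
              detrend="constant"):
    """One-sided Welch power spectral density of a rate series.

    Returns ``(freqs_hz, psd)``.  Used both to characterize SW/AW regimes
    (delta-band power, adaptation resonances) and as the cross-simulator
    validation statistic.
    """
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = min(x.size, 256)
    if x.size < nperseg or x.size < 2:
        raise ValueError("series shorter than one Welch segment")
    return sps.welch(x, fs=fs_hz, window=window, nperseg=nperseg,
                     noverlap=noverlap, detrend=detrend, scaling="density")


# --------------------------------------------------------------------------
# MUA / logMUA

@dataclass
class MUAGrid:
    """Per-module MUA(t) on the grid, and the derived logMUA."""

    times_ms: np.ndarray  # bin centers
    mua_hz: np.ndarray  # (n_bins, rows, cols)
    bin_ms: float
    imd_mm: float
    log_mua: np.ndarray | None = None  # (n_bins, rows, cols)
    mua_down_hz: np.ndarray | None = None  # per module
    threshold: np.ndarray | None = None  # per module, logMUA units

    @property
    def shape(self):
        return self.mua_hz.shape[1:]


def compute_mua(record: SpikeRecord, spec: GridSpec, bin_ms: float = 5.0) -> MUAGrid:
    """Module-average firing rate on the grid: the simulated MUA proxy."""
    rs = bin_rates(record, spec, bin_ms=bin_ms, grouping="module")
    mua = rs.rates_hz.reshape(-1, spec.rows, spec.cols)
    return MUAGrid(times_ms=rs.centers_ms, mua_hz=mua, bin_ms=bin_ms,
                   imd_mm=spec.imd_mm)


def _bimodal_threshold(values: np.ndarray, n_hist: int = 48,
                       min_separation: float = 0.8) -> float | None:
    """Midpoint between the two dominant modes of a histogram, or None.

    A genuine Up/Down signal separates its modes by the log rate ratio
    (typically >= 1); candidate modes closer than ``min_separation`` (log
    units) or without a clear dip between them are rejected as unimodal.
    """
    h, edges = np.histogram(values, bins=n_hist)
    k = np.ones(3) / 3.0
    hs = np.convolve(h, k, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [i for i in range(1, n_hist - 1)
             if hs[i] >= hs[i - 1] and hs[i] >= hs[i + 1] and hs[i] > 0]
    # merge plateau-adjacent peaks
    dom = sorted(peaks, key=lambda i: -hs[i])
    sel = []
    for i in dom:
        if all(abs(i - j) > 3 for j in sel):
            sel.append(i)
        if len(sel) == 2:
            break
    if len(sel) < 2:
        return None
    lo, hi = sorted(sel)
    if centers[hi] - centers[lo] < min_separation:
        return None
    # demand a real dip between the modes
    dip = hs[lo:hi + 1].min()
    if dip > 0.6 * min(hs[lo], hs[hi]):
        return None
    return float(0.5 * (centers[lo] + centers[hi]))


def log_mua(grid: MUAGrid, noise_variance: float = 0.5, seed: int = 0,
            floor_hz: float = 0.1, n_bootstrap: int = 2) -> MUAGrid:
    """Log-ratio MUA against the Down-state baseline, plus emulation noise.

    ``logMUA = log(MUA / MUA_down) + N(0, noise_variance)`` per sample.
    ``MUA_down`` (per module) is bootstrapped: starting from the samples
    below the 30th percentile, the detection threshold (midpoint between the
    two modes of the logMUA histogram) and the Down-sample mean are iterated
    ``n_bootstrap`` times.  Zero activity is floored at ``floor_hz`` before
    the log so silent bins stay finite.
    """
    x = np.maximum(grid.mua_hz, floor_hz)
    n_bins, rows, cols = x.shape
    flat = x.reshape(n_bins, -1)
    mua_down = np.empty(rows * cols)
    thr = np.empty(rows * cols)
    for m in range(rows * cols):
        v = flat[:, m]
        guess = np.quantile(v, 0.30)
        down = v <= guess
        if not down.any():
            down = v <= np.median(v)
        md = v[down].mean()
        t_m = None
        for _ in range(n_bootstrap):
            logm = np.log(v / md)
            t_m = _bimodal_threshold(logm)
            if t_m is None:
                break
            down = logm < t_m
            if down.any():
                md = v[down].mean()
        mua_down[m] = md
        thr[m] = t_m if t_m is not None else np.inf
    if mua_down.min() <= 0:
        raise ValueError("MUA_down must be positive")
    logm = np.log(flat / mua_down[None, :])
    rng = np.random.default_rng([seed, 0x106A])
    if noise_variance > 0:
        logm = logm + rng.normal(0.0, math.sqrt(noise_variance), size=logm.shape)
    out = MUAGrid(times_ms=grid.times_ms, mua_hz=grid.mua_hz, bin_ms=grid.bin_ms,
                  imd_mm=grid.imd_mm)
    out.log_mua = logm.reshape(n_bins, rows, cols)
    out.mua_down_hz = mua_down.reshape(rows, cols)
    out.threshold = thr.reshape(rows, cols)
    return out


# --------------------------------------------------------------------------
# transition detection and wavefront speed

@dataclass
class WavefrontMap:
    """One wave: Down-to-Up transition time per module (NaN where absent)."""

    T_ms: np.ndarray  # (rows, cols)
    imd_mm: float
    wave_id: int = 0

    @property
    def coverage(self) -> float:
        return float(np.isfinite(self.T_ms).mean())


def detect_transitions(grid: MUAGrid, smooth_bins: int = 4,
                       gap_ms: float = 200.0, min_coverage: float = 0.25,
                       threshold: np.ndarray | float | None = None,
                       min_companions: int | None = None,
                       companion_ms: float = 30.0) -> list:
    """Detect Down-to-Up transitions and cluster them into waves.

    Per module, the (optionally smoothed) logMUA is scanned for upward
    crossings of the module's threshold, with linear sub-bin interpolation of
    the crossing time.  Crossings across the whole grid are sorted in time
    and split into discrete waves wherever the gap exceeds ``gap_ms``
    (configurable; the slow-wave cycle is a few hundred ms).  Each wave keeps
    one transition time per module (the earliest).  Waves covering less than
    ``min_coverage`` of the grid are dropped.  A stationary (AW-like) signal
    yields no crossings and an empty list.
    """
    if grid.mua_down_hz is None:
        raise ValueError("run log_mua first")
    n_bins, rows, cols = grid.mua_hz.shape
    # detection signal: log-ratio of the SMOOTHED rate against the Down
    # baseline.  Smoothing the rate before the log tames the shot noise of
    # small modules (single spikes make the per-bin log flicker by whole
    # log-units), which would otherwise swamp the Up/Down bimodality.
    mua = grid.mua_hz.reshape(n_bins, -1)
    if smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        mua = np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), 0, mua)
    floor = 0.1
    x = np.log(np.maximum(mua, floor) / grid.mua_down_hz.reshape(1, -1))
    if threshold is None:
        # per-module threshold from the bimodality of the scanned signal
        thr = np.array([
            t if (t := _bimodal_threshold(x[:, m])) is not None else np.inf
            for m in range(rows * cols)
        ])
    elif np.isscalar(threshold):
        thr = np.full(rows * cols, float(threshold))
    else:
        thr = np.asarray(threshold, float).reshape(-1)
    t = grid.times_ms
    cross_t, cross_m = [], []
    for m in range(rows * cols):
        if not np.isfinite(thr[m]):
            continue
        v = x[:, m]
        up = np.flatnonzero((v[:-1] < thr[m]) & (v[1:] >= thr[m]))
        for i in up:
            frac = (thr[m] - v[i]) / (v[i + 1] - v[i])
            cross_t.append(t[i] + frac * (t[i + 1] - t[i]))
            cross_m.append(m)
    if not cross_t:
        return []
    cross_t = np.asarray(cross_t)
    cross_m = np.asarray(cross_m)
    order = np.argsort(cross_t, kind="stable")
    cross_t, cross_m = cross_t[order], cross_m[order]
    if min_companions is None:
        min_companions = max(2, (rows * cols) // 10)
    if min_companions > 0 and cross_t.size > min_companions:
        # a wavefront is collective: drop isolated crossings (fewer than
        # min_companions other modules crossing within +-companion_ms),
        # which otherwise bridge the temporal gaps between waves
        lo = np.searchsorted(cross_t, cross_t - companion_ms, side="left")
        hi = np.searchsorted(cross_t, cross_t + companion_ms, side="right")
        keep = (hi - lo - 1) >= min_companions
        cross_t, cross_m = cross_t[keep], cross_m[keep]
        if cross_t.size == 0:
            return []
    # segment the pooled crossing train into waves: cut at silent gaps and
    # at deep valleys of the crossing-density trace (waves that follow each
    # other closely, e.g. regional waves at long connectivity range, are
    # separated by density minima rather than by silence)
    cut = np.diff(cross_t) > gap_ms
    dens_bin = 10.0
    edges = np.arange(cross_t[0] - dens_bin, cross_t[-1] + 2 * dens_bin, dens_bin)
    dens = np.histogram(cross_t, bins=edges)[0].astype(float)
    dens = np.convolve(dens, np.ones(3) / 3.0, mode="same")
    interior = np.arange(1, dens.size - 1)
    is_min = (dens[interior] <= dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    for i in interior[is_min]:
        left_pk = dens[:i].max() if i > 0 else 0.0
        right_pk = dens[i + 1:].max() if i + 1 < dens.size else 0.0
        if min(left_pk, right_pk) > 0 and dens[i] < 0.25 * min(left_pk, right_pk):
            t_cut = edges[i] + 0.5 * dens_bin
            j = np.searchsorted(cross_t, t_cut)
            if 0 < j < cross_t.size:
                cut[j - 1] = True
    breaks = np.flatnonzero(cut)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [cross_t.size]])
    waves = []
    wid = 0
    for s, e in zip(starts, ends):
        T = np.full(rows * cols, np.nan)
        for ti, mi in zip(cross_t[s:e], cross_m[s:e]):
            if not np.isfinite(T[mi]):  # earliest crossing wins
                T[mi] = ti
        wmap = WavefrontMap(T_ms=T.reshape(rows, cols), imd_mm=grid.imd_mm,
                            wave_id=wid)
        if wmap.coverage >= min_coverage:
            waves.append(wmap)
            wid += 1
    return waves


@dataclass
class SpeedStats:
    mean_mm_s: float
    sd_mm_s: float
    mean_imd_s: float
    n_points: int
    n_excluded: int
    per_wave_mm_s: np.ndarray
    speed_fields_mm_s: list = field(default_factory=list)


def speed_imd_to_mm_per_s(speed_imd_per_ms: float, imd_mm: float) -> float:
    """Unit chain: imd/ms -> mm/s (x imd_mm, x 1000)."""
    return speed_imd_per_ms * imd_mm * 1000.0


def wavefront_speed(waves, imd_mm: float | None = None,
                    exclude_border: bool = True,
                    min_gradient_ms: float = 0.0) -> SpeedStats:
    """Speed statistics from transition-time maps.

    ``V = 1/|grad T|`` pointwise (central differences inside, one-sided at
    the grid edges); the border ring is excluded from the averages by default
    (open-boundary artifacts), as are undefined points (NaN neighbours) and
    zero-gradient points, which are counted in ``n_excluded``.

    ``min_gradient_ms`` extends the zero-gradient exclusion to gradients
    below the temporal resolution of the transition times (about half the
    MUA bin width per module): such points are indistinguishable from
    simultaneous and carry no finite speed.
    """
    if isinstance(waves, WavefrontMap):
        waves = [waves]
    if not waves:
        raise ValueError("no waves to measure")
    vals = []
    per_wave = []
    fields = []
    n_excluded = 0
    for w in waves:
        T = w.T_ms
        if T.shape[0] < 3 or T.shape[1] < 3:
            raise ValueError("transition map must cover at least 3x3 modules")
        mm = imd_mm if imd_mm is not None else w.imd_mm
        gy, gx = np.gradient(T)  # ms per imd
        grad = np.hypot(gx, gy)
        with np.errstate(divide="ignore", invalid="ignore"):
            V = 1.0 / grad  # imd per ms
        V_mm = speed_imd_to_mm_per_s(V, mm)
        sel = np.isfinite(V_mm) & (grad > max(min_gradient_ms, 0.0))
        if min_gradient_ms <= 0:
            sel &= grad > 0
        if exclude_border:
            border = np.zeros_like(sel)
            border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
            sel &= ~border
            interior_total = (T.shape[0] - 2) * (T.shape[1] - 2)
        else:
            interior_total = T.size
        n_excluded += interior_total - int(sel.sum())
        fields.append(np.where(sel, V_mm, np.nan))
        if sel.any():
            vals.append(V_mm[sel])
            per_wave.append(float(V_mm[sel].mean()))
    if not vals:
        raise ValueError("no valid speed points (flat or undefined gradients)")
    allv = np.concatenate(vals)
    mm = imd_mm if imd_mm is not None else waves[0].imd_mm
    return SpeedStats(
        mean_mm_s=float(allv.mean()),
        sd_mm_s=float(allv.std()),
        mean_imd_s=float(allv.mean() / mm),
        n_points=int(allv.size),
        n_excluded=int(n_excluded),
        per_wave_mm_s=np.asarray(per_wave),
        speed_fields_mm_s=fields,
    )
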