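"""Shared fixtures: desk-scale slow-wave and asynchronous reference runs.

The spiking runs are the expensive part of the suite, so they are produced
once per session and shared by every test that inspects them.
"""

import numpy as np
import pytest

from gridwave import analysis, engine, workbench

SW_LAMBDAS = (0.4, 0.5, 0.6, 0.7)
SW_DURATION_MS = 4000.0
AW_DURATION_MS = 4000.0
SEED = 20


def run_sw(lam: float, seed: int = SEED, duration_ms: float = SW_DURATION_MS):
    """One mini-SW run at the given connectivity range, plus its wave stats."""
    cfg = workbench.preset("mini-SW")
    doc = cfg.to_document()
    doc["kernel.lambda_imd"] = lam
    doc["run.seed"] = seed
    cfg = workbench.validate_config(doc)
    net = workbench.build_network(cfg)
    rec = engine.run(net, duration_ms, seed=seed, init="rest")
    bin_ms = 2.0
    mua = analysis.compute_mua(rec, cfg.grid, bin_ms=bin_ms)
    mua = analysis.log_mua(mua, noise_variance=cfg.logmua_noise_var, seed=seed)
    waves = analysis.detect_transitions(mua, smooth_bins=int(20 / bin_ms),
                                        gap_ms=120.0)
    full = [w for w in waves if w.coverage >= 0.8]
    out = {
        "record": rec,
        "config": cfg,
        "waves": waves,
        "full_waves": full,
        "wave_rate_hz": len(full) / (duration_ms * 1e-3),
    }
    if len(full) >= 2:
        out["speed"] = analysis.wavefront_speed(full, min_gradient_ms=bin_ms / 2)
    return out


@pytest.fixture(scope="session")
def sw_sweep():
    """mini-SW runs for every connectivity decay constant of the study."""
    return {lam: run_sw(lam) for lam in SW_LAMBDAS}


@pytest.fixture(scope="session")
def aw_run():
    """One mini-AW run with its population rates after the transient."""
    cfg = workbench.preset("mini-AW")
    net = workbench.build_network(cfg, seed=SEED)
    rec = engine.run(net, AW_DURATION_MS, seed=SEED, init="spread")
    rates = analysis.bin_rates(rec, cfg.grid, bin_ms=cfg.bin_ms, grouping="pop")
    transient = int(500 / cfg.bin_ms)
    return {
        "record": rec,
        "config": cfg,
        "pop_rates_hz": rates.rates_hz[transient:].mean(axis=0),
    }
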