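"""Shared fixtures: toy germline references and analyzed simulations.

The expensive objects (simulated repertoires run through the full
pipeline) are session-scoped so many tests can interrogate one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ovig.pipeline import PipelineConfig, analyze_reads
from ovig.simulate import make_toy_germline, simulate_repertoire
from ovig.types import SimulationConfig

TOY_SEED = 7


@pytest.fixture(scope="session")
def igh_ref():
    return make_toy_germline(seed=TOY_SEED, locus="IGH", n_v=4, n_d=4, n_j=2)


@pytest.fixture(scope="session")
def igk_ref():
    return make_toy_germline(seed=9, locus="IGK", n_v=3, n_d=0, n_j=2)


def _run(ref, cfg, locus="IGH"):
    reads, truth = simulate_repertoire(cfg, ref)
    res = analyze_reads(reads, ref, PipelineConfig(min_len=300, locus=locus))
    return {
        "config": cfg,
        "reads": reads,
        "truth": truth,
        "by_id": {t.read_id: t for t in truth},
        **res,
    }


@pytest.fixture(scope="session")
def run_shm0(igh_ref):
    """1000 IGH reads, no SHM, no sequencing error: the clean-junction
    conditions under which boundary recovery is exact."""
    cfg = SimulationConfig(seed=101, n_reads=1000, shm_rate=0.0,
                           seq_error_rate=0.0)
    return _run(igh_ref, cfg)


@pytest.fixture(scope="session")
def run_shm2(igh_ref):
    """800 IGH reads at 2% SHM (no hotspot bias) for mutation recovery,
    rate and spectrum checks."""
    cfg = SimulationConfig(seed=102, n_reads=800, shm_rate=0.02,
                           hotspot_multiplier=1.0, seq_error_rate=0.0)
    return _run(igh_ref, cfg)


@pytest.fixture(scope="session")
def run_hotspot(igh_ref):
    """800 IGH reads at 2% SHM with fivefold AID-hotspot enrichment."""
    cfg = SimulationConfig(seed=103, n_reads=800, shm_rate=0.02,
                           hotspot_multiplier=5.0, seq_error_rate=0.0)
    return _run(igh_ref, cfg)


@pytest.fixture(scope="session")
def run_usage(igh_ref):
    """1500 IGH reads with skewed V usage for multinomial recovery."""
    cfg = SimulationConfig(
        seed=104, n_reads=1500, shm_rate=0.0,
        usage_weights_v={"IGHV1": 0.6, "IGHV2": 0.3, "IGHV3": 0.1, "IGHV4": 0.0},
    )
    return _run(igh_ref, cfg)


def binom_3se(p: float, n: int) -> float:
    return 3.0 * np.sqrt(max(p * (1 - p), 1e-12) / n)
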