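"""Shared fixtures: toy genome, simulated genomes, stub models, and one
session-scoped end-to-end pipeline run (simulate -> train -> rebalance ->
mine) reused by the slower integration checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from splicescan import (
    ExonRecord,
    GenomeSequence,
    ModelSpec,
    SimConfig,
    simulate_genome,
)
from splicescan.simulator import LengthDist

settings.register_profile(
    "splicescan",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("splicescan")

# Toy 40-nt genome with one 2-exon transcript: exons [1,6] and [28,40],
# giving a canonical donor at 6 (GT at 7-8) and acceptor at 27 (AG at 26-27).
TOY_SEQ = "CCCATGGTAAGTTTTTTTTTTTTTCAGGCCGCCTAATAAA"


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence("x", TOY_SEQ)


@pytest.fixture
def toy_exons() -> list[ExonRecord]:
    return [
        ExonRecord("x", "g1", "t1", 1, 6, "+"),
        ExonRecord("x", "g1", "t1", 28, 40, "+"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A compact annotated genome for scanner/dataset tests."""
    cfg = SimConfig(
        n_genes=8,
        exons_per_gene=5,
        exon_len=LengthDist(60, 0.25, minimum=12),
        intron_len=LengthDist(80, 0.25, minimum=30),
        intergenic_len=LengthDist(250, 0.3, minimum=60),
        non_canonical_fraction=0.1,
        seed=42,
    )
    genome, exons, sites = simulate_genome(cfg)
    return genome, exons, sites


@dataclass
class StubModel:
    """Duck-typed model emitting a constant class distribution."""

    spec: ModelSpec
    label_order: tuple = ("acceptor", "donor", "non_splice")
    constant: tuple = (0.0, 0.0, 1.0)

    def predict_proba(self, windows, batch_size: int = 1024):
        n = len(windows) if hasattr(windows, "__len__") else windows.shape[0]
        if hasattr(windows, "shape"):
            n = windows.shape[0]
        return np.tile(np.asarray(self.constant, dtype=float), (n, 1))


@pytest.fixture
def stub_model_factory():
    def make(L=20, constant=(0.0, 0.0, 1.0), label_order=None):
        kwargs = {}
        if label_order is not None:
            kwargs["label_order"] = tuple(label_order)
        return StubModel(
            spec=ModelSpec(L=L, kernels=2, kernel_size=3, fc_units=2),
            constant=constant,
            **kwargs,
        )

    return make


@pytest.fixture(scope="session")
def e2e():
    """Run the reference end-to-end study protocol once (simulate -> train
    -> rebalance -> mine -> scan); reused by the integration tests."""
    from splicescan.protocols import run_end_to_end

    return run_end_to_end(11)
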