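"""Canned study protocols: the package's reference end-to-end experiment.

The desk-scale study conditions are a ~190 kb forward-strand genome of 40
compact genes with 26 exons each (1000 donor and 1000 acceptor junctions),
GT/AG decoy pseudo-motifs planted at 1 per kb so that hard-negative mining
has genuine false positives to harvest, and 5% of introns non-canonical
(GC-AG / AT-AC) so the rebalancing and non-canonical recovery stages have
material to work with. Windows are L=100 nt, 1000 per class, trained for
20 epochs per fit; the mining loop runs 3 iterations against a set-aside
evaluation gene that contains at least one non-canonical junction.
"""

from __future__ import annotations

import numpy as np

from .cnn_model import ModelSpec, SpliceCNN, TrainConfig
from .dataset import build_initial_dataset, rebalance_positive_set, split_dataset
from .mining import MiningConfig, gene_regions, iterative_reconstruction
from .scanner import scan_sequence
from .simulator import LengthDist, SimConfig, simulate_genome

E2E_L = 100
E2E_EPOCHS = 20
E2E_N_PER_CLASS = 1000
E2E_MINING_ITERATIONS = 3


def e2e_sim_config(seed: int) -> SimConfig:
    return SimConfig(
        n_genes=40,
        exons_per_gene=26,
        exon_len=LengthDist(80, 0.3, minimum=12),
        intron_len=LengthDist(90, 0.3, minimum=30),
        intergenic_len=LengthDist(400, 0.4, minimum=60),
        non_canonical_fraction=0.05,
        decoy_rate=1.0,
        seed=seed,
    )


def run_end_to_end(seed: int) -> dict:
    """Simulate, train, rebalance, mine and scan; return all artifacts.

    Every stage's randomness derives from ``seed``.
    """
    base = np.random.default_rng(seed)
    sim_seed, data_seed, split_seed, train_seed, reb_seed, mine_seed = (
        int(s) for s in base.integers(2**31, size=6)
    )

    genome, exons, sites = simulate_genome(e2e_sim_config(sim_seed))
    dataset = build_initial_dataset(
        sites, genome, E2E_L, E2E_N_PER_CLASS, seed=data_seed
    )
    train_set, val_set, test_set = split_dataset(dataset, seed=split_seed)
    model = SpliceCNN(ModelSpec(L=E2E_L))
    model.fit(
        train_set.encode(model.label_order),
        val_set.encode(model.label_order),
        TrainConfig(epochs=E2E_EPOCHS, seed=train_seed),
    )

    rebalanced = rebalance_positive_set(dataset, ratio=10, seed=reb_seed)
    regions = gene_regions(exons, genome, E2E_L)
    non_canonical = [s for s in sites if not s.canonical]
    eval_region = next(
        r
        for _, r in sorted(regions.items(), key=lambda kv: kv[1].start)
        if any(r.start <= s.boundary <= r.end for s in non_canonical)
    )
    final_dataset, final_model, records = iterative_reconstruction(
        rebalanced,
        genome,
        exons,
        eval_region,
        ModelSpec(L=E2E_L),
        MiningConfig(
            max_iterations=E2E_MINING_ITERATIONS,
            patience=E2E_MINING_ITERATIONS,
            seed=mine_seed,
            train=TrainConfig(epochs=E2E_EPOCHS, seed=mine_seed),
        ),
    )
    eval_calls = scan_sequence(final_model, genome, eval_region, min_score=0.5)
    return {
        "genome": genome,
        "exons": exons,
        "sites": sites,
        "dataset": dataset,
        "rebalanced": rebalanced,
        "test_set": test_set,
        "model": model,
        "eval_region": eval_region,
        "final_dataset": final_dataset,
        "final_model": final_model,
        "records": records,
        "eval_calls": eval_calls,
    }
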