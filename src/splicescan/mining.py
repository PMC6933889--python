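"""Iterative hard-negative mining (dataset reconstruction).

A classifier trained on midpoint negatives tends to call every GT/AG-like
position a splice site when slid along a real sequence. The reconstruction
loop sharpens it: train on the current dataset, scan one annotated gene,
collect the false-positive calls as new ``non_splice`` windows, retrain,
and repeat until the false-positive count on a set-aside evaluation region
stops decreasing. Positives never change; the negative set grows
monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cnn_model import ModelSpec, SpliceCNN, TrainConfig
from .dataset import (
    ACCEPTOR,
    DONOR,
    NON_SPLICE,
    LabeledWindow,
    SpliceDataset,
    extract_window,
)
from .errors import CapacityError, ConfigError
from .scanner import SiteCall, scan_sequence
from .sequence_io import ExonRecord, GenomeSequence, Region, SpliceSite


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    mined_region: str
    n_new_fps: int
    negative_set_size: int
    eval_fp_count: int
    eval_recall: float
    test_accuracy: float


@dataclass(frozen=True)
class MiningConfig:
    max_iterations: int = 100
    patience: int = 3
    min_relative_decrease: float = 0.0
    seed: int = 0
    test_frac: float = 0.10
    match_tolerance: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    warm_start: bool = False

    def __post_init__(self):
        if self.max_iterations < 1 or self.patience < 1:
            raise ConfigError("max_iterations and patience must be >= 1")


def mine_false_positives(
    model: SpliceCNN,
    genome: GenomeSequence,
    region: Region,
    annotated_sites: Sequence[SpliceSite],
    L: int,
    existing_negatives: Optional[Iterable[tuple[str, int]]] = None,
    match_tolerance: int = 0,
    step: int = 1,
) -> list[LabeledWindow]:
    """Positions the model calls donor/acceptor that are not annotated.

    Each false positive becomes a ``non_splice`` window centered at the
    called position, tagged with the class it was predicted as. Mined
    windows are de-duplicated against ``existing_negatives`` (a set of
    (seq_name, boundary) keys) and within the call list itself.
    """
    if region.length < L:
        raise ConfigError(f"mining region {region} shorter than window length {L}")
    annotated = {
        site_type: sorted(
            s.boundary
            for s in annotated_sites
            if s.seq_name == genome.name and s.site_type == site_type
        )
        for site_type in (DONOR, ACCEPTOR)
    }

    def is_true_site(call: SiteCall) -> bool:
        boundaries = annotated[call.site_type]
        if not boundaries:
            return False
        i = np.searchsorted(boundaries, call.boundary)
        for j in (i - 1, i):
            if 0 <= j < len(boundaries):
                if abs(boundaries[j] - call.boundary) <= match_tolerance:
                    return True
        return False

    seen: set[tuple[str, int]] = set(existing_negatives or ())
    mined: list[LabeledWindow] = []
    for call in scan_sequence(model, genome, region, L=L, step=step):
        if is_true_site(call):
            continue
        key = (call.seq_name, call.boundary)
        if key in seen:
            continue
        seen.add(key)
        mined.append(
            LabeledWindow(
                seq_name=call.seq_name,
                boundary=call.boundary,
                sequence=extract_window(genome, call.boundary, L),
                label=NON_SPLICE,
                canonical=None,
                predicted_as=call.site_type,
            )
        )
    return mined


def evaluate_region(
    model: SpliceCNN,
    genome: GenomeSequence,
    region: Region,
    annotated_sites: Sequence[SpliceSite],
    L: int,
    match_tolerance: int = 0,
) -> tuple[int, float, list[SiteCall]]:
    """(false-positive count, recall, calls) of an argmax scan of a region."""
    calls = scan_sequence(model, genome, region, L=L)
    true_sites = [
        s
        for s in annotated_sites
        if s.seq_name == genome.name and region.start <= s.boundary <= region.end
    ]
    truth_keys = {(s.site_type, s.boundary) for s in true_sites}
    n_fp = 0
    matched: set[tuple[str, int]] = set()
    for call in calls:
        hit = None
        for site_type, boundary in truth_keys:
            if site_type == call.site_type and abs(boundary - call.boundary) <= match_tolerance:
                hit = (site_type, boundary)
                break
        if hit is None:
            n_fp += 1
        else:
            matched.add(hit)
    recall = len(matched) / len(truth_keys) if truth_keys else float("nan")
    return n_fp, recall, calls


def gene_regions(
    exons: Sequence[ExonRecord],
    genome: GenomeSequence,
    L: int,
    margin: int | None = None,
) -> dict[str, Region]:
    """One scanning region per gene: its exon span padded by ``margin``."""
    margin = L if margin is None else margin
    spans: dict[str, tuple[int, int]] = {}
    for e in exons:
        if e.seq_name != genome.name:
            continue
        lo, hi = spans.get(e.gene_id, (e.start, e.end))
        spans[e.gene_id] = (min(lo, e.start), max(hi, e.end))
    return {
        gid: Region(
            genome.name,
            max(1, lo - margin),
            min(genome.length, hi + margin),
        )
        for gid, (lo, hi) in sorted(spans.items())
    }


def _regions_overlap(a: Region, b: Region) -> bool:
    return a.seq_name == b.seq_name and a.start <= b.end and b.start <= a.end


def _stalled(fp_history: Sequence[int], patience: int, min_rel: float) -> bool:
    """True when the last ``patience`` values failed to beat the running best."""
    if len(fp_history) <= patience:
        return False
    streak = 0
    best = fp_history[0]
    for value in fp_history[1:]:
        if value < best * (1.0 - min_rel):
            streak = 0
        else:
            streak += 1
        best = min(best, value)
    return streak >= patience


def iterative_reconstruction(
    dataset: SpliceDataset,
    genome: GenomeSequence,
    annotation: Sequence[ExonRecord] | Sequence[SpliceSite],
    eval_region: Region,
    spec: ModelSpec,
    config: MiningConfig = MiningConfig(),
    annotated_sites: Optional[Sequence[SpliceSite]] = None,
    checkpoint_callback=None,
    start_iteration: int = 0,
    prior_fp_history: Sequence[int] = (),
) -> tuple[SpliceDataset, SpliceCNN, list[IterationRecord]]:
    """Run the dataset-reconstruction loop.

    Windows falling inside ``eval_region`` are dropped from the starting
    dataset so the set-aside region never contributes training material.
    Per iteration: retrain from freshly initialized weights on 90% of the
    current dataset (per-iteration seed), measure accuracy on the held-out
    10%, count false positives and recall on the set-aside ``eval_region``,
    then mine one randomly chosen annotated gene (never one overlapping
    the evaluation region) and append its false positives to the negative
    set. Stops once the evaluation false-positive count has failed to
    improve on its running best for ``patience`` consecutive iterations,
    or at ``max_iterations``.

    ``start_iteration``/``prior_fp_history`` let a caller resume a stopped
    loop deterministically: per-iteration seeds depend only on
    (config.seed, iteration index).
    """
    from .sequence_io import extract_splice_sites  # local to avoid cycle at import

    exons = [e for e in annotation if isinstance(e, ExonRecord)]
    if annotated_sites is None:
        if exons:
            annotated_sites = extract_splice_sites(exons, genome)
        else:
            annotated_sites = [s for s in annotation if isinstance(s, SpliceSite)]
    if not exons:
        raise CapacityError("iterative reconstruction needs exon annotation "
                            "to choose mining regions")

    regions = {
        gid: r
        for gid, r in gene_regions(exons, genome, dataset.L).items()
        if not _regions_overlap(r, eval_region) and r.length >= dataset.L
    }
    if not regions:
        raise CapacityError("no annotated gene regions outside the evaluation "
                            "region are available for mining")
    region_ids = sorted(regions)

    held_out = [
        w
        for w in dataset.windows
        if w.seq_name == eval_region.seq_name
        and eval_region.start <= w.boundary <= eval_region.end
    ]
    if held_out:
        held = set(held_out)
        dataset = SpliceDataset(
            windows=[w for w in dataset.windows if w not in held],
            L=dataset.L,
            provenance={**dataset.provenance,
                        "eval_region_excluded": len(held_out)},
            allow_duplicates=dataset.allow_duplicates,
        )

    neg_keys = {
        (w.seq_name, w.boundary) for w in dataset.windows if w.label == NON_SPLICE
    }
    current = dataset
    records: list[IterationRecord] = []
    fp_history: list[int] = list(prior_fp_history)
    model: Optional[SpliceCNN] = None

    for iteration in range(start_iteration + 1,
                           start_iteration + config.max_iterations + 1):
        rng = np.random.default_rng([config.seed, iteration])
        split_seed = int(rng.integers(2**31))
        train_seed = int(rng.integers(2**31))

        train_set, test_set = _stratified_two_way(
            current, config.test_frac, split_seed
        )
        if model is None or not config.warm_start:
            model = SpliceCNN(spec)
        train_cfg = TrainConfig(
            learning_rate=config.train.learning_rate,
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            seed=train_seed,
        )
        model.fit(train_set.encode(model.label_order), None, train_cfg)
        test_accuracy = model.evaluate_accuracy(test_set.encode(model.label_order))

        eval_fp, eval_recall, _ = evaluate_region(
            model, genome, eval_region, annotated_sites, current.L,
            config.match_tolerance,
        )

        gene_id = region_ids[int(rng.integers(len(region_ids)))]
        mined = mine_false_positives(
            model,
            genome,
            regions[gene_id],
            annotated_sites,
            current.L,
            existing_negatives=neg_keys,
            match_tolerance=config.match_tolerance,
        )
        neg_keys.update((w.seq_name, w.boundary) for w in mined)
        current = SpliceDataset(
            windows=list(current.windows) + mined,
            L=current.L,
            provenance={**current.provenance, "mining_iteration": iteration},
            allow_duplicates=current.allow_duplicates,
        )

        records.append(
            IterationRecord(
                iteration=iteration,
                mined_region=str(regions[gene_id]),
                n_new_fps=len(mined),
                negative_set_size=sum(
                    1 for w in current.windows if w.label == NON_SPLICE
                ),
                eval_fp_count=eval_fp,
                eval_recall=eval_recall,
                test_accuracy=test_accuracy,
            )
        )
        if checkpoint_callback is not None:
            checkpoint_callback(iteration, model, current, records[-1])
        fp_history.append(eval_fp)
        if _stalled(fp_history, config.patience, config.min_relative_decrease):
            break

    return current, model, records


def _stratified_two_way(
    dataset: SpliceDataset, test_frac: float, seed: int
) -> tuple[SpliceDataset, SpliceDataset]:
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted({w.label for w in dataset.windows}):
        stratum = [w for w in dataset.windows if w.label == label]
        n_test = max(1, int(round(len(stratum) * test_frac)))
        order = rng.permutation(len(stratum))
        test.extend(stratum[i] for i in order[:n_test])
        train.extend(stratum[i] for i in order[n_test:])
    mk = lambda w, name: SpliceDataset(
        windows=w,
        L=dataset.L,
        provenance={**dataset.provenance, "split": name},
        allow_duplicates=dataset.allow_duplicates,
    )
    return mk(train, "mining_train"), mk(test, "mining_test")


def write_iteration_log(records: Iterable[IterationRecord], path):
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame.to_csv(path, sep="\t", index=False)


def read_iteration_log(path) -> list[IterationRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        IterationRecord(
            iteration=int(r.iteration),
            mined_region=str(r.mined_region),
            n_new_fps=int(r.n_new_fps),
            negative_set_size=int(r.negative_set_size),
            eval_fp_count=int(r.eval_fp_count),
            eval_recall=float(r.eval_recall),
            test_accuracy=float(r.test_accuracy),
        )
        for r in frame.itertuples()
    ]
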