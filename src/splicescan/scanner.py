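"""Sliding-window localization of splice sites on long sequences.

Every candidate boundary position in a region is classified through the
3-class model; positions whose top class is donor or acceptor become
:class:`SiteCall`s. Because the model only answers positively when the
junction sits at the window center, step-1 scanning recovers exact site
positions. Two optional 2-class filter models (site vs false positive,
same architecture except the 2-unit output layer) can re-score calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cnn_model import ModelSpec, SpliceCNN, TrainConfig
from .dataset import (
    ACCEPTOR,
    DONOR,
    EncodedBatch,
    LabeledWindow,
    encode_batch,
)
from .errors import CapacityError, ConfigError
from .sequence_io import GenomeSequence, Region

FALSE_POSITIVE = "false_positive"


@dataclass(frozen=True)
class SiteCall:
    seq_name: str
    boundary: int
    site_type: str  # "donor" | "acceptor"
    score: float
    passed_filter: Optional[bool] = None
    filter_score: Optional[float] = None


def candidate_boundaries(
    genome: GenomeSequence, region: Region | None, L: int, step: int = 1
) -> np.ndarray:
    """Step-strided boundary positions in ``region`` with a full window."""
    if step < 1:
        raise ConfigError("step must be >= 1")
    half = L // 2
    lo = half  # smallest boundary with full left context (b - L/2 + 1 >= 1)
    hi = genome.length - half
    if region is not None:
        lo = max(lo, region.start)
        hi = min(hi, region.end)
    if hi < lo:
        return np.zeros(0, dtype=np.int64)
    return np.arange(lo, hi + 1, step, dtype=np.int64)


def scan_sequence(
    model: SpliceCNN,
    genome: GenomeSequence,
    region: Region | None = None,
    L: int | None = None,
    step: int = 1,
    min_score: float = 0.0,
    batch_size: int = 1024,
) -> list[SiteCall]:
    """Classify every candidate boundary; emit donor/acceptor calls.

    Equivalent (exactly) to extracting each window independently and
    running the model on it; the batching here only amortizes the
    convolution. Output is sorted by boundary.
    """
    L = L if L is not None else model.spec.L
    if L != model.spec.L:
        raise ConfigError(f"L={L} does not match model input length {model.spec.L}")
    if region is not None and region.length < L:
        raise ConfigError(
            f"region {region} shorter than the window length {L}"
        )
    positions = candidate_boundaries(genome, region, L, step)
    label_index = {lab: i for i, lab in enumerate(model.label_order)}
    calls: list[SiteCall] = []
    half = L // 2
    for lo in range(0, len(positions), batch_size):
        batch_pos = positions[lo : lo + batch_size]
        windows = [genome.seq[p - half : p + half] for p in batch_pos]
        probs = model.predict_proba(encode_batch(windows))
        top = probs.argmax(axis=1)
        for p, cls, prob_row in zip(batch_pos, top, probs):
            label = model.label_order[cls]
            if label not in (DONOR, ACCEPTOR):
                continue
            score = float(prob_row[label_index[label]])
            if score >= min_score:
                calls.append(SiteCall(genome.name, int(p), label, score))
    return calls


def train_binary_filters(
    positive_windows: Sequence[LabeledWindow],
    mined_fp_windows: Sequence[LabeledWindow],
    spec: ModelSpec,
    config: TrainConfig,
) -> tuple[SpliceCNN, SpliceCNN]:
    """Train the donor and acceptor site-vs-false-positive filters.

    Each filter shares the main architecture but ends in a 2-unit softmax.
    A filter's positives are the positive windows of its class; its
    negatives are the mined false positives that were *predicted* as that
    class (``predicted_as``), falling back to all mined windows when no
    prediction provenance is recorded.
    """
    filters = []
    binary_spec = dc_replace(spec, n_classes=2)
    for site_type in (DONOR, ACCEPTOR):
        pos = [w for w in positive_windows if w.label == site_type]
        neg = [w for w in mined_fp_windows if w.predicted_as == site_type]
        if not neg:
            neg = [w for w in mined_fp_windows if w.predicted_as is None]
        if not pos or not neg:
            raise CapacityError(
                f"cannot train {site_type} filter: {len(pos)} positives, "
                f"{len(neg)} mined false positives"
            )
        x = encode_batch([w.sequence for w in pos + neg])
        y = np.array([1] * len(pos) + [0] * len(neg), dtype=np.int64)
        model = SpliceCNN(binary_spec, label_order=(FALSE_POSITIVE, site_type))
        model.fit(EncodedBatch(x=x, y=y), None, config)
        filters.append(model)
    return filters[0], filters[1]


def filter_calls(
    calls: Sequence[SiteCall],
    donor_filter,
    acceptor_filter,
    genome: GenomeSequence,
    L: int,
    min_filter_score: float = 0.5,
) -> list[SiteCall]:
    """Re-score calls with the matching binary filter; keep those passing.

    A contraction: never adds calls, never changes boundaries or types.
    """
    filters = {DONOR: donor_filter, ACCEPTOR: acceptor_filter}
    half = L // 2
    out: list[SiteCall] = []
    for call in calls:
        flt = filters.get(call.site_type)
        if flt is None:
            raise ConfigError(f"no filter configured for {call.site_type!r} calls")
        window = genome.seq[call.boundary - half : call.boundary + half]
        probs = flt.predict_proba(encode_batch([window]))[0]
        site_index = list(flt.label_order).index(call.site_type)
        score = float(probs[site_index])
        passed = score >= min_filter_score
        if passed:
            out.append(
                SiteCall(
                    call.seq_name,
                    call.boundary,
                    call.site_type,
                    call.score,
                    passed_filter=True,
                    filter_score=score,
                )
            )
    return out


def non_maximum_suppression(calls: Sequence[SiteCall], radius: int) -> list[SiteCall]:
    """Keep only the best-scoring call within +-radius nt per site type.

    Off by default in the scanner; trained models often fire on a few
    neighboring offsets around a true junction.
    """
    kept: list[SiteCall] = []
    for site_type in (DONOR, ACCEPTOR):
        group = sorted(
            (c for c in calls if c.site_type == site_type),
            key=lambda c: -c.score,
        )
        chosen: list[SiteCall] = []
        for call in group:
            if all(abs(call.boundary - k.boundary) > radius for k in chosen):
                chosen.append(call)
        kept.extend(chosen)
    return sorted(kept, key=lambda c: (c.seq_name, c.boundary, c.site_type))


def write_calls_tsv(calls: Iterable[SiteCall], path):
    frame = pd.DataFrame(
        [
            {
                "seq_name": c.seq_name,
                "boundary": c.boundary,
                "site_type": c.site_type,
                "score": c.score,
                "passed_filter": "" if c.passed_filter is None else c.passed_filter,
            }
            for c in calls
        ],
        columns=["seq_name", "boundary", "site_type", "score", "passed_filter"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[SiteCall]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in frame.itertuples():
        passed = None
        if str(row.passed_filter) != "":
            passed = str(row.passed_filter) == "True"
        out.append(
            SiteCall(
                seq_name=str(row.seq_name),
                boundary=int(row.boundary),
                site_type=str(row.site_type),
                score=float(row.score),
                passed_filter=passed,
            )
        )
    return out


def write_calls_bed(calls: Iterable[SiteCall], path):
    """BED6: 0-based half-open single-base intervals, score scaled 0-1000."""
    with open(path, "w") as handle:
        for c in calls:
            handle.write(
                "\t".join(
                    [
                        c.seq_name,
                        str(c.boundary - 1),
                        str(c.boundary),
                        c.site_type,
                        str(int(round(c.score * 1000))),
                        "+",
                    ]
                )
                + "\n"
            )
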