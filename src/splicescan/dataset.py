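"""Window extraction, one-hot encoding and 3-class dataset construction.

The classifier sees fixed-length windows of length ``L`` (even). A window
for boundary ``b`` covers genome positions ``b - L/2 + 1 .. b + L/2``, so
the junction sits exactly between window positions ``L/2`` and ``L/2 + 1``
(for L=400, between 200 and 201). Positive windows are centered on donor
or acceptor boundaries; the initial negatives are centered at the midpoint
between adjacent annotated boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    CapacityError,
    ConfigError,
    CoordinateError,
)
from .sequence_io import (
    ACCEPTOR,
    DONOR,
    GenomeSequence,
    SpliceSite,
    _as_genome_map,
)

NON_SPLICE = "non_splice"

# Fixed integer label order, recorded in saved models.
LABEL_ORDER: tuple[str, ...] = (ACCEPTOR, DONOR, NON_SPLICE)
LABEL_TO_INDEX = {name: i for i, name in enumerate(LABEL_ORDER)}

# One-hot code: A=(1,0,0,0), C=(0,1,0,0), G=(0,0,1,0), T=(0,0,0,1), N=zeros.
_BASES = "ACGT"
_ENCODE_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(_BASES):
    _ENCODE_LUT[ord(_b), _i] = 1.0
_VALID_LUT = np.zeros(256, dtype=bool)
for _b in "ACGTN":
    _VALID_LUT[ord(_b)] = True


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as an (L, 4) matrix (channels A, C, G, T)."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    if not _VALID_LUT[raw].all():
        bad = sorted({chr(c) for c in raw[~_VALID_LUT[raw]]})
        raise AlphabetError(f"cannot encode characters {bad!r}")
    return _ENCODE_LUT[raw].copy()


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L, 4) array."""
    if not sequences:
        return np.zeros((0, 0, 4), dtype=np.float32)
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ConfigError(f"mixed sequence lengths {sorted(lengths)} in batch")
    return np.stack([one_hot_encode(s) for s in sequences])


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(_BASES[int(np.argmax(row))])
    return "".join(out)


def extract_window(genome: GenomeSequence, boundary: int, L: int) -> str:
    """The length-L window whose center junction is at ``boundary``."""
    if L % 2 != 0 or L < 2:
        raise ConfigError(f"window length must be a positive even number, got {L}")
    start = boundary - L // 2 + 1
    end = boundary + L // 2
    if start < 1 or end > genome.length:
        raise CoordinateError(
            f"window {start}..{end} for boundary {boundary} overruns "
            f"sequence {genome.name!r} (length {genome.length})"
        )
    return genome.seq[start - 1 : end]


def window_fits(genome: GenomeSequence, boundary: int, L: int) -> bool:
    return boundary - L // 2 + 1 >= 1 and boundary + L // 2 <= genome.length


@dataclass(frozen=True)
class LabeledWindow:
    seq_name: str
    boundary: int
    sequence: str
    label: str  # "donor" | "acceptor" | "non_splice"
    canonical: Optional[bool] = None  # None for non_splice windows
    predicted_as: Optional[str] = None  # for mined false positives

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.seq_name, self.boundary, self.label)


@dataclass(frozen=True)
class EncodedBatch:
    x: np.ndarray  # (n, L, 4)
    y: np.ndarray  # (n,) integer labels


@dataclass
class SpliceDataset:
    """Labeled fixed-length windows with construction provenance."""

    windows: list[LabeledWindow]
    L: int
    provenance: dict = field(default_factory=dict)
    allow_duplicates: bool = False

    def __post_init__(self):
        for w in self.windows:
            if len(w.sequence) != self.L:
                raise ConfigError(
                    f"window at {w.seq_name}:{w.boundary} has length "
                    f"{len(w.sequence)}, expected L={self.L}"
                )
        if not self.allow_duplicates:
            keys = [w.key for w in self.windows]
            if len(set(keys)) != len(keys):
                raise ConfigError("duplicate (seq_name, boundary, label) windows")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(w.label for w in self.windows)
        return {label: counts.get(label, 0) for label in LABEL_ORDER}

    def subset(self, labels: Iterable[str]) -> "SpliceDataset":
        labels = set(labels)
        return replace(
            self,
            windows=[w for w in self.windows if w.label in labels],
            provenance={**self.provenance, "subset": sorted(labels)},
        )

    def encode(self, label_order: Sequence[str] = LABEL_ORDER) -> EncodedBatch:
        index = {name: i for i, name in enumerate(label_order)}
        x = encode_batch([w.sequence for w in self.windows])
        y = np.array([index[w.label] for w in self.windows], dtype=np.int64)
        return EncodedBatch(x=x, y=y)

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq_name": w.seq_name,
                    "boundary": w.boundary,
                    "label": w.label,
                    "canonical": "" if w.canonical is None else w.canonical,
                    "predicted_as": w.predicted_as or "",
                }
                for w in self.windows
            ],
            columns=["seq_name", "boundary", "label", "canonical", "predicted_as"],
        )

    def to_manifest(self, path):
        """TSV manifest; window sequences are rebuilt from FASTA on load."""
        with open(path, "w") as handle:
            handle.write(f"#L={self.L}\n")
            self.manifest_frame().to_csv(handle, sep="\t", index=False)

    @classmethod
    def from_manifest(cls, path, genome, L: int | None = None) -> "SpliceDataset":
        genomes = _as_genome_map(genome)
        with open(path) as handle:
            first = handle.readline()
            if first.startswith("#L="):
                L = int(first[3:].strip())
            else:
                handle.seek(0)
                if L is None:
                    raise ConfigError("manifest lacks #L= header and no L given")
            frame = pd.read_csv(handle, sep="\t", keep_default_na=False)
        windows = []
        for row in frame.itertuples():
            g = genomes[str(row.seq_name)]
            canonical = None
            if str(row.canonical) != "":
                canonical = str(row.canonical) == "True"
            windows.append(
                LabeledWindow(
                    seq_name=str(row.seq_name),
                    boundary=int(row.boundary),
                    sequence=extract_window(g, int(row.boundary), L),
                    label=str(row.label),
                    canonical=canonical,
                    predicted_as=str(row.predicted_as) or None,
                )
            )
        return cls(windows=windows, L=L, provenance={"source": str(path)},
                   allow_duplicates=True)


def negative_midpoints(
    sites: Sequence[SpliceSite],
    genomes: Mapping[str, GenomeSequence],
    L: int,
) -> list[tuple[str, int]]:
    """Candidate non-splice centers: midpoints between adjacent boundaries.

    For adjacent annotated boundaries ``b_i < b_{i+1}`` on one sequence the
    candidate is ``floor((b_i + b_{i+1}) / 2)``; midpoints that coincide
    with an annotated boundary or whose window overruns the sequence are
    dropped.
    """
    per_seq: dict[str, set[int]] = {}
    for s in sites:
        per_seq.setdefault(s.seq_name, set()).add(s.boundary)
    out: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for seq_name in sorted(per_seq):
        boundaries = sorted(per_seq[seq_name])
        g = genomes[seq_name]
        for b1, b2 in zip(boundaries, boundaries[1:]):
            mid = (b1 + b2) // 2
            if mid in per_seq[seq_name]:
                continue
            if not window_fits(g, mid, L):
                continue
            key = (seq_name, mid)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def build_initial_dataset(
    sites: Sequence[SpliceSite],
    genome,
    L: int,
    n_per_class: int,
    seed: int = 0,
    max_n_fraction: float = 1.0,
) -> SpliceDataset:
    """Sample the initial 3-class dataset from annotated sites.

    ``n_per_class`` donor and acceptor windows are drawn uniformly without
    replacement from the sites whose window fits the genome, and
    ``n_per_class`` negatives from midpoints between adjacent boundaries.
    Deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    genomes = _as_genome_map(genome)
    rng = np.random.default_rng(seed)

    def n_fraction(seq: str) -> float:
        return seq.count("N") / len(seq)

    pools: dict[str, list[LabeledWindow]] = {}
    for site_type in (DONOR, ACCEPTOR):
        pool = []
        for s in sorted(x for x in sites if x.site_type == site_type):
            g = genomes[s.seq_name]
            if not window_fits(g, s.boundary, L):
                continue
            seq = extract_window(g, s.boundary, L)
            if n_fraction(seq) > max_n_fraction:
                continue
            pool.append(
                LabeledWindow(s.seq_name, s.boundary, seq, site_type, s.canonical)
            )
        pools[site_type] = pool

    neg_pool = []
    for seq_name, mid in negative_midpoints(sites, genomes, L):
        seq = extract_window(genomes[seq_name], mid, L)
        if n_fraction(seq) > max_n_fraction:
            continue
        neg_pool.append(LabeledWindow(seq_name, mid, seq, NON_SPLICE, None))
    pools[NON_SPLICE] = neg_pool

    windows: list[LabeledWindow] = []
    for label in LABEL_ORDER:
        pool = pools[label]
        if len(pool) < n_per_class:
            raise CapacityError(
                f"requested {n_per_class} {label} windows but only "
                f"{len(pool)} are extractable"
            )
        chosen = rng.choice(len(pool), size=n_per_class, replace=False)
        windows.extend(pool[i] for i in np.sort(chosen))

    return SpliceDataset(
        windows=windows,
        L=L,
        provenance={
            "source": "build_initial_dataset",
            "seed": seed,
            "n_per_class": n_per_class,
        },
    )


def rebalance_positive_set(
    dataset: SpliceDataset,
    ratio: int = 10,
    seed: int = 0,
    oversample_non_canonical: bool = False,
    max_non_canonical_per_class: int | None = None,
) -> SpliceDataset:
    """Enforce a canonical:non-canonical ratio within each positive class.

    By default all available non-canonical positives are kept (up to the
    per-class cap) and canonical positives are subsampled to exactly
    ``ratio`` times the kept non-canonical count; when canonical windows
    are too few for that, the kept non-canonical count is lowered so the
    exact ratio still holds. With ``oversample_non_canonical`` the
    non-canonical windows are instead resampled with replacement up to
    ``n_canonical // ratio``. Negatives are untouched.
    """
    if ratio < 1:
        raise ConfigError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list[LabeledWindow] = [w for w in dataset.windows if w.label == NON_SPLICE]
    duplicated = False
    for label in (ACCEPTOR, DONOR):
        canonical = [w for w in dataset.windows
                     if w.label == label and w.canonical]
        non_canonical = [w for w in dataset.windows
                         if w.label == label and w.canonical is False]
        if not non_canonical:
            raise CapacityError(
                f"no non-canonical {label} windows available for rebalancing"
            )
        if oversample_non_canonical:
            n_nc = max(1, len(canonical) // ratio)
            idx = rng.choice(len(non_canonical), size=n_nc, replace=True)
            nc_keep = [non_canonical[i] for i in idx]
            duplicated = duplicated or n_nc > len(set(idx.tolist()))
        else:
            n_nc = len(non_canonical)
            if max_non_canonical_per_class is not None:
                n_nc = min(n_nc, max_non_canonical_per_class)
            n_nc = min(n_nc, len(canonical) // ratio)
            if n_nc < 1:
                raise CapacityError(
                    f"cannot keep ratio {ratio}:1 for {label}: "
                    f"{len(canonical)} canonical / {len(non_canonical)} "
                    "non-canonical windows"
                )
            idx = rng.choice(len(non_canonical), size=n_nc, replace=False)
            nc_keep = [non_canonical[i] for i in np.sort(idx)]
        n_can = ratio * len(nc_keep)
        idx = rng.choice(len(canonical), size=n_can, replace=False)
        kept.extend(canonical[i] for i in np.sort(idx))
        kept.extend(nc_keep)
    return SpliceDataset(
        windows=kept,
        L=dataset.L,
        provenance={
            **dataset.provenance,
            "rebalanced_ratio": ratio,
            "rebalance_seed": seed,
        },
        allow_duplicates=duplicated or dataset.allow_duplicates,
    )


def split_dataset(
    dataset: SpliceDataset,
    test_frac: float = 0.10,
    val_frac_of_train: float = 0.20,
    seed: int = 0,
) -> tuple[SpliceDataset, SpliceDataset, SpliceDataset]:
    """Stratified (train, validation, test) partition.

    Per label stratum, ``round(n * test_frac)`` windows go to the test
    split and ``round(n_remaining * val_frac_of_train)`` of the rest to
    validation. The three splits are disjoint and exhaustive.
    """
    if not (0 < test_frac < 1) or not (0 < val_frac_of_train < 1):
        raise ConfigError("split fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for label in LABEL_ORDER:
        stratum = [w for w in dataset.windows if w.label == label]
        if not stratum:
            continue
        n = len(stratum)
        n_test = int(round(n * test_frac))
        n_val = int(round((n - n_test) * val_frac_of_train))
        if n_test < 1 or n_val < 1 or n - n_test - n_val < 1:
            raise CapacityError(
                f"stratum {label!r} with {n} windows is too small for a "
                "non-empty train/validation/test split"
            )
        order = rng.permutation(n)
        test.extend(stratum[i] for i in order[:n_test])
        val.extend(stratum[i] for i in order[n_test : n_test + n_val])
        train.extend(stratum[i] for i in order[n_test + n_val :])

    def make(windows, name):
        return SpliceDataset(
            windows=windows,
            L=dataset.L,
            provenance={**dataset.provenance, "split": name, "split_seed": seed},
            allow_duplicates=dataset.allow_duplicates,
        )

    return make(train, "train"), make(val, "validation"), make(test, "test")
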