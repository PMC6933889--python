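"""Synthetic multi-gene genomes with known splice-site ground truth.

Genes are laid left to right on a single forward-strand sequence with
intergenic gaps. Each intron's two junctions carry motif bases sampled
from position probability matrices: a 9-column donor motif spanning the
last 3 exonic and first 6 intronic bases (consensus MAG|GTRAGT, GT fixed)
and a 15-column acceptor motif spanning the last 14 intronic and first
exonic base (pyrimidine tract then NYAG|G, AG fixed). A configurable
fraction of introns is made non-canonical by substituting the terminal
dimers consistently at both ends (GC-AG or AT-AC). An optional decoy rate
plants additional GT/AG-bearing pseudo-motifs away from real junctions so
that hard-negative mining has genuine false positives to collect.

The emitted FASTA + GTF + ground-truth site list are mutually consistent:
deriving sites from the annotation reproduces the ground truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .errors import CapacityError, ConfigError
from .sequence_io import (
    ACCEPTOR,
    DONOR,
    ExonRecord,
    GenomeSequence,
    SpliceSite,
    _is_canonical,
)

_BASES = np.array(list("ACGT"))

# Donor position probability matrix: columns exon -3..-1 | intron +1..+6.
# Values are hand-set to resemble the textbook MAG|GTRAGT consensus; no
# motif model is prescribed for this simulator, only GT/AG determinism.
DEFAULT_DONOR_PWM = np.array(
    [
        # A     C     G     T
        [0.35, 0.35, 0.18, 0.12],  # -3  M
        [0.60, 0.12, 0.14, 0.14],  # -2  A
        [0.09, 0.05, 0.79, 0.07],  # -1  G
        [0.00, 0.00, 1.00, 0.00],  # +1  G (fixed)
        [0.00, 0.00, 0.00, 1.00],  # +2  T (fixed)
        [0.55, 0.03, 0.38, 0.04],  # +3  R
        [0.68, 0.09, 0.11, 0.12],  # +4  A
        [0.09, 0.06, 0.78, 0.07],  # +5  G
        [0.16, 0.16, 0.20, 0.48],  # +6  T
    ]
)
DONOR_EXON_COLS = 3  # columns left of the junction

# Acceptor PPM: columns intron -14..-1 | exon +1 (pyrimidine tract, NYAG|G).
_PY = [0.08, 0.32, 0.08, 0.52]  # pyrimidine-tract column
DEFAULT_ACCEPTOR_PWM = np.array(
    [_PY] * 9
    + [
        [0.10, 0.30, 0.10, 0.50],  # -5  Y
        [0.25, 0.25, 0.25, 0.25],  # -4  N
        [0.05, 0.65, 0.05, 0.25],  # -3  Y
        [1.00, 0.00, 0.00, 0.00],  # -2  A (fixed)
        [0.00, 0.00, 1.00, 0.00],  # -1  G (fixed)
        [0.50, 0.12, 0.25, 0.13],  # +1  G/A
    ]
)
ACCEPTOR_EXON_COLS = 1  # columns right of the junction


@dataclass(frozen=True)
class LengthDist:
    """Log-normal integer length distribution with hard bounds.

    ``mean`` is the distribution mean in nucleotides; ``sigma`` the shape
    of the underlying normal (0 makes the length deterministic).
    """

    mean: float
    sigma: float = 0.35
    minimum: int = 1
    maximum: Optional[int] = None

    def __post_init__(self):
        if self.mean < self.minimum:
            raise ConfigError(
                f"length mean {self.mean} below minimum {self.minimum}"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sigma == 0:
            vals = np.full(size, int(round(self.mean)))
        else:
            mu = math.log(self.mean) - self.sigma**2 / 2
            vals = np.rint(rng.lognormal(mu, self.sigma, size)).astype(int)
        vals = np.maximum(vals, self.minimum)
        if self.maximum is not None:
            vals = np.minimum(vals, self.maximum)
        return vals


@dataclass(frozen=True, eq=False)
class SimConfig:
    n_genes: int = 20
    exons_per_gene: Optional[int] = None  # fixed count; None => shifted Poisson
    mean_exons_per_gene: float = 6.0  # used when exons_per_gene is None, min 2
    exon_len: LengthDist = field(default_factory=lambda: LengthDist(150, 0.35, minimum=12))
    intron_len: LengthDist = field(default_factory=lambda: LengthDist(450, 0.45, minimum=30))
    intergenic_len: LengthDist = field(default_factory=lambda: LengthDist(700, 0.45, minimum=60))
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    donor_pwm: np.ndarray = field(default_factory=lambda: DEFAULT_DONOR_PWM.copy())
    acceptor_pwm: np.ndarray = field(
        default_factory=lambda: DEFAULT_ACCEPTOR_PWM.copy()
    )
    non_canonical_fraction: float = 0.01
    non_canonical_dimers: tuple[tuple[str, str], ...] = (("GC", "AG"), ("AT", "AC"))
    decoy_rate: float = 0.0  # expected pseudo-motifs per kb
    alt_splicing: bool = False
    chrom_name: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        donor_pwm = np.asarray(self.donor_pwm, dtype=float)
        acceptor_pwm = np.asarray(self.acceptor_pwm, dtype=float)
        object.__setattr__(self, "donor_pwm", donor_pwm)
        object.__setattr__(self, "acceptor_pwm", acceptor_pwm)
        for name, pwm in (("donor", donor_pwm), ("acceptor", acceptor_pwm)):
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ConfigError(f"{name}_pwm must have shape (columns, 4)")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ConfigError(f"{name}_pwm columns must each sum to 1")
        if not np.isclose(sum(self.background), 1.0, atol=1e-6):
            raise ConfigError("background composition must sum to 1")
        if not (0 <= self.non_canonical_fraction <= 1):
            raise ConfigError("non_canonical_fraction must lie in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.exons_per_gene is not None and self.exons_per_gene < 2:
            raise ConfigError("exons_per_gene must be >= 2")
        donor_intron = donor_pwm.shape[0] - DONOR_EXON_COLS
        acceptor_intron = acceptor_pwm.shape[0] - ACCEPTOR_EXON_COLS
        if self.intron_len.minimum < donor_intron + acceptor_intron:
            raise ConfigError(
                f"intron minimum {self.intron_len.minimum} shorter than the "
                f"junction motif span {donor_intron + acceptor_intron}"
            )
        if self.exon_len.minimum < DONOR_EXON_COLS + ACCEPTOR_EXON_COLS:
            raise ConfigError("exon minimum shorter than the exonic motif bases")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimConfig):
            return NotImplemented
        from dataclasses import fields as dc_fields

        for f in dc_fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True

    def to_yaml(self, path=None) -> str:
        data = {
            "n_genes": self.n_genes,
            "exons_per_gene": self.exons_per_gene,
            "mean_exons_per_gene": self.mean_exons_per_gene,
            "exon_len": vars_of(self.exon_len),
            "intron_len": vars_of(self.intron_len),
            "intergenic_len": vars_of(self.intergenic_len),
            "background": list(self.background),
            "donor_pwm": self.donor_pwm.tolist(),
            "acceptor_pwm": self.acceptor_pwm.tolist(),
            "non_canonical_fraction": self.non_canonical_fraction,
            "non_canonical_dimers": [list(p) for p in self.non_canonical_dimers],
            "decoy_rate": self.decoy_rate,
            "alt_splicing": self.alt_splicing,
            "chrom_name": self.chrom_name,
            "seed": self.seed,
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and len(text) < 4096:
                with open(text) as handle:
                    data = yaml.safe_load(handle)
            else:
                data = yaml.safe_load(text)
        for key in ("exon_len", "intron_len", "intergenic_len"):
            if key in data and isinstance(data[key], dict):
                data[key] = LengthDist(**data[key])
        if "background" in data:
            data["background"] = tuple(data["background"])
        if "non_canonical_dimers" in data:
            data["non_canonical_dimers"] = tuple(
                tuple(p) for p in data["non_canonical_dimers"]
            )
        for key in ("donor_pwm", "acceptor_pwm"):
            if key in data:
                data[key] = np.asarray(data[key], dtype=float)
        return cls(**data)


def vars_of(dist: LengthDist) -> dict:
    return {
        "mean": dist.mean,
        "sigma": dist.sigma,
        "minimum": dist.minimum,
        "maximum": dist.maximum,
    }


_DIMER_IDX = {b: i for i, b in enumerate("ACGT")}


def _sample_background(rng, n, composition) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(composition))


def _sample_pwm(rng, pwm) -> np.ndarray:
    return np.array([rng.choice(4, p=col) for col in pwm])


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[ExonRecord], list[SpliceSite]]:
    """Generate (genome, exon annotation, ground-truth splice sites).

    Fully deterministic for a given config (including the seed); the
    ground truth equals what the extractor derives from the emitted
    FASTA + GTF.
    """
    rng = np.random.default_rng(config.seed)
    donor_pwm = config.donor_pwm
    acceptor_pwm = config.acceptor_pwm
    donor_intron_cols = donor_pwm.shape[0] - DONOR_EXON_COLS
    acceptor_intron_cols = acceptor_pwm.shape[0] - ACCEPTOR_EXON_COLS

    chunks: list[np.ndarray] = []
    exons: list[ExonRecord] = []
    truth: list[tuple[int, str]] = []  # (boundary, site_type)
    # protect junction motif spans and exons from decoy overwrites
    protected: list[tuple[int, int]] = []
    pos = 1  # next unwritten 1-based genome coordinate

    for gene_index in range(config.n_genes):
        gap = int(config.intergenic_len.sample(rng, 1)[0])
        chunks.append(_sample_background(rng, gap, config.background))
        pos += gap

        if config.exons_per_gene is not None:
            k = config.exons_per_gene
        else:
            k = 2 + int(rng.poisson(max(config.mean_exons_per_gene - 2, 0)))
        exon_lens = config.exon_len.sample(rng, k)
        intron_lens = config.intron_len.sample(rng, k - 1)

        gene_len = int(exon_lens.sum() + intron_lens.sum())
        gene = _sample_background(rng, gene_len, config.background)
        gene_start = pos

        # exon coordinates within the gene (0-based offsets)
        exon_coords = []
        offset = 0
        for i in range(k):
            exon_coords.append((offset, offset + int(exon_lens[i]) - 1))
            offset += int(exon_lens[i])
            if i < k - 1:
                offset += int(intron_lens[i])

        gene_id = f"g{gene_index + 1}"
        for start0, end0 in exon_coords:
            exons.append(
                ExonRecord(
                    seq_name=config.chrom_name,
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    start=gene_start + start0,
                    end=gene_start + end0,
                    strand="+",
                )
            )
        if config.alt_splicing and k >= 3:
            skip = 1 + int(rng.integers(k - 2))  # an internal exon
            for i, (start0, end0) in enumerate(exon_coords):
                if i == skip:
                    continue
                exons.append(
                    ExonRecord(
                        seq_name=config.chrom_name,
                        gene_id=gene_id,
                        transcript_id=f"{gene_id}.t2",
                        start=gene_start + start0,
                        end=gene_start + end0,
                        strand="+",
                    )
                )

        for i in range(k - 1):
            donor_b0 = exon_coords[i][1]  # 0-based last exonic base
            acceptor_b0 = exon_coords[i + 1][0] - 1  # 0-based last intronic base
            # plant motifs
            d_lo = donor_b0 - DONOR_EXON_COLS + 1
            gene[d_lo : d_lo + donor_pwm.shape[0]] = _sample_pwm(rng, donor_pwm)
            a_lo = acceptor_b0 - acceptor_intron_cols + 1
            gene[a_lo : a_lo + acceptor_pwm.shape[0]] = _sample_pwm(rng, acceptor_pwm)
            # occasionally make the intron non-canonical at both ends
            if rng.random() < config.non_canonical_fraction:
                d_dimer, a_dimer = config.non_canonical_dimers[
                    int(rng.integers(len(config.non_canonical_dimers)))
                ]
                gene[donor_b0 + 1] = _DIMER_IDX[d_dimer[0]]
                gene[donor_b0 + 2] = _DIMER_IDX[d_dimer[1]]
                gene[acceptor_b0 - 1] = _DIMER_IDX[a_dimer[0]]
                gene[acceptor_b0] = _DIMER_IDX[a_dimer[1]]
            truth.append((gene_start + donor_b0, DONOR))
            truth.append((gene_start + acceptor_b0, ACCEPTOR))
            protected.append(
                (gene_start + d_lo, gene_start + d_lo + donor_pwm.shape[0] - 1)
            )
            protected.append(
                (gene_start + a_lo, gene_start + a_lo + acceptor_pwm.shape[0] - 1)
            )
        for start0, end0 in exon_coords:
            protected.append((gene_start + start0, gene_start + end0))

        chunks.append(gene)
        pos += gene_len

    tail = int(config.intergenic_len.sample(rng, 1)[0])
    chunks.append(_sample_background(rng, tail, config.background))
    sequence = np.concatenate(chunks)

    if config.decoy_rate > 0:
        _plant_decoys(rng, sequence, protected, config)

    genome = GenomeSequence(config.chrom_name, "".join(_BASES[sequence]))
    sites = sorted(
        SpliceSite(
            seq_name=config.chrom_name,
            boundary=boundary,
            site_type=site_type,
            canonical=_is_canonical(genome, boundary, site_type),
        )
        for boundary, site_type in set(truth)
    )
    return genome, exons, sites


def _plant_decoys(rng, sequence: np.ndarray, protected, config: SimConfig):
    """Overwrite random unprotected spans with PWM-sampled pseudo-motifs."""
    n_decoys = int(rng.poisson(config.decoy_rate * len(sequence) / 1000.0))
    if n_decoys == 0:
        return
    blocked = np.zeros(len(sequence) + 2, dtype=bool)
    for lo, hi in protected:
        blocked[max(lo - 1, 0) : hi] = True  # to 0-based
    pwms = (config.donor_pwm, config.acceptor_pwm)
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < n_decoys * 20:
        attempts += 1
        pwm = pwms[int(rng.integers(2))]
        span = pwm.shape[0]
        start0 = int(rng.integers(len(sequence) - span))
        if blocked[start0 : start0 + span].any():
            continue
        sequence[start0 : start0 + span] = _sample_pwm(rng, pwm)
        blocked[start0 : start0 + span] = True
        placed += 1


def simulate_dataset_genome(
    target_sites_per_type: int,
    config: Optional[SimConfig] = None,
    exons_per_gene: int = 11,
    **overrides,
) -> tuple[GenomeSequence, list[ExonRecord], list[SpliceSite], dict]:
    """Size a genome so each site type count reaches a target.

    With ``exons_per_gene`` fixed exons per gene each gene contributes
    ``exons_per_gene - 1`` junctions of each type, so
    ``n_genes = ceil(target / (exons_per_gene - 1))``. Returns the genome,
    annotation, ground truth and an info dict with the achieved counts.
    """
    if target_sites_per_type < 1:
        raise ConfigError("target must be >= 1")
    base = config if config is not None else SimConfig()
    n_genes = -(-target_sites_per_type // (exons_per_gene - 1))
    cfg = replace(
        base, n_genes=n_genes, exons_per_gene=exons_per_gene, **overrides
    )
    genome, exons, sites = simulate_genome(cfg)
    counts = {
        DONOR: sum(1 for s in sites if s.site_type == DONOR),
        ACCEPTOR: sum(1 for s in sites if s.site_type == ACCEPTOR),
    }
    for site_type, count in counts.items():
        if count < target_sites_per_type:
            raise CapacityError(
                f"sized genome yields only {count} {site_type} sites "
                f"for target {target_sites_per_type}"
            )
    info = {
        "n_genes": n_genes,
        "exons_per_gene": exons_per_gene,
        "achieved_counts": counts,
        "genome_length": genome.length,
    }
    return genome, exons, sites, info
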