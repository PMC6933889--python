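"""Per-nucleotide contribution scores and sequence-logo matrices.

Contribution scores are gradient x input against an all-zero reference:
``score(i, c) = input(i, c) * d(logit_target)/d(input(i, c))``. For ReLU
networks with a zero baseline this coincides with the Rescale-rule
backpropagated contributions in the non-saturating case, and it is exact
for linear models (the scores sum to ``logit(x) - logit(0)``). Pre-softmax
logits are attributed rather than probabilities, which avoids saturation
artifacts once the model is confident. Per-position scores sum the four
channels; one-hot rows have a single nonzero term, N rows contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import encode_batch, one_hot_encode
from .errors import CapacityError, ConfigError, ShapeError

_BASES = "ACGT"


@dataclass(frozen=True)
class ContributionProfile:
    positions: np.ndarray  # 1-based window positions, junction +- flank
    mean_score: np.ndarray
    n_sequences: int
    target_class: str


def _class_index(model, target_class) -> int:
    if isinstance(target_class, str):
        if target_class not in model.label_order:
            raise ConfigError(
                f"class {target_class!r} not in model label order "
                f"{model.label_order}"
            )
        return list(model.label_order).index(target_class)
    return int(target_class)


def contribution_scores(model, window, target_class) -> np.ndarray:
    """(L, 4) gradient-x-input scores for one window."""
    x = one_hot_encode(window) if isinstance(window, str) else np.asarray(window)
    if x.shape != (model.spec.L, 4):
        raise ShapeError(
            f"window of shape {x.shape} does not match model input "
            f"({model.spec.L}, 4)"
        )
    grad = model.input_gradient(x[None], _class_index(model, target_class))[0]
    return x * grad


def per_position_scores(score_matrix: np.ndarray) -> np.ndarray:
    """Collapse (L, 4) channel scores to one score per position."""
    return np.asarray(score_matrix).sum(axis=1)


def flank_positions(L: int, flank: int = 10) -> np.ndarray:
    """The 1-based window positions within ``flank`` of the center junction.

    The junction lies between positions L/2 and L/2+1, so the default
    flank of 10 selects positions L/2-9 .. L/2+10 (191..210 for L=400).
    """
    half = L // 2
    if flank < 1 or half - flank + 1 < 1:
        raise ConfigError(f"flank {flank} invalid for window length {L}")
    return np.arange(half - flank + 1, half + flank + 1)


def average_profile(
    model, windows: Sequence, target_class, flank: int = 10
) -> ContributionProfile:
    """Mean per-position contribution over windows, junction +- flank."""
    if not len(windows):
        raise CapacityError("average_profile needs at least one window")
    seqs = [w.sequence if hasattr(w, "sequence") else w for w in windows]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ShapeError(f"mixed window lengths {sorted(lengths)}")
    L = lengths.pop()
    positions = flank_positions(L, flank)
    idx = positions - 1
    x = encode_batch(seqs)
    grad = model.input_gradient(x, _class_index(model, target_class))
    per_pos = (x * grad).sum(axis=2)  # (n, L)
    return ContributionProfile(
        positions=positions,
        mean_score=per_pos[:, idx].mean(axis=0),
        n_sequences=len(seqs),
        target_class=str(target_class),
    )


def logo_matrix(
    windows: Sequence, flank: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column nucleotide frequencies and information content near the junction.

    Returns ``(positions, frequencies, information)`` where frequencies is
    a (2*flank, 4) matrix over A,C,G,T (N rows are excluded from the
    counts) and information(j) = 2 + sum_c p log2 p bits, in [0, 2].
    """
    if not len(windows):
        raise CapacityError("logo_matrix needs at least one window")
    seqs = [w.sequence if hasattr(w, "sequence") else w for w in windows]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ShapeError(f"mixed window lengths {sorted(lengths)}")
    L = lengths.pop()
    positions = flank_positions(L, flank)
    counts = np.zeros((len(positions), 4))
    for seq in seqs:
        for row, pos in enumerate(positions):
            base = seq[pos - 1]
            if base != "N":
                counts[row, _BASES.index(base)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    information = np.where(totals[:, 0] > 0, 2.0 + plogp.sum(axis=1), 0.0)
    return positions, freqs, information


def write_profile_tsv(profile: ContributionProfile, path):
    import pandas as pd

    pd.DataFrame(
        {"position": profile.positions, "mean_score": profile.mean_score}
    ).to_csv(path, sep="\t", index=False)


def write_logo_tsv(positions, freqs, information, path):
    import pandas as pd

    frame = pd.DataFrame(freqs, columns=list(_BASES))
    frame.insert(0, "position", positions)
    frame["information_bits"] = information
    frame.to_csv(path, sep="\t", index=False)


def plot_logo(positions, freqs, information, path=None, ax=None):
    """Render a simple stacked-bar sequence logo (heights scaled by IC)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * len(positions), 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for row, pos in enumerate(positions):
        bottom = 0.0
        order = np.argsort(freqs[row])
        for k in order:
            height = freqs[row, k] * information[row]
            if height <= 0:
                continue
            ax.bar(pos, height, bottom=bottom, color=colors[_BASES[k]], width=0.9)
            bottom += height
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("window position")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
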