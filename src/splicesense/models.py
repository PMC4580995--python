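"""Position-weight models for splice-signal scoring.

A :class:`PositionWeightModel` is a first-order (position-independent
columns) log-odds model: the score of a k-mer is

    sum_i log2( p_i(base_i) / background(base_i) )

Scores from different models are not comparable; analyses must use a single
model for every sequence they compare (the same-scorer-both-species rule).
Models round-trip through a plain-text TSV so externally trained tables can
be plugged in.

The shipped defaults are consensus-frequency models for the mammalian donor
9-mer (3 exonic + 6 intronic nt), acceptor 23-mer (20 intronic + 3 exonic nt)
and branch-point heptamer (yUnAy-type consensus with the branch adenosine at
position 6).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "PositionWeightModel",
    "default_donor_model",
    "default_acceptor_model",
    "default_branch_model",
    "train_pwm",
]

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}


class PositionWeightModel:
    """First-order position-weight model with log2-odds scoring."""

    def __init__(self, probs: np.ndarray, background: np.ndarray | None = None):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (k, 4)")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive")
        self.probs = probs / probs.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        self.background = np.asarray(background, dtype=float)
        self._logodds = np.log2(self.probs / self.background)

    @property
    def k(self) -> int:
        return self.probs.shape[0]

    def score(self, kmer: str) -> float:
        kmer = kmer.upper()
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} nt")
        total = 0.0
        for i, base in enumerate(kmer):
            j = _INDEX.get(base)
            if j is None:
                raise ValueError(f"non-ACGT base {base!r} at position {i}")
            total += self._logodds[i, j]
        return float(total)

    @classmethod
    def uniform(cls, k: int) -> "PositionWeightModel":
        """Background-identical model; scores 0 for every k-mer."""
        return cls(np.full((k, 4), 0.25))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(BASES) + "\n")
            for i, row in enumerate(self.probs):
                fh.write(f"{i}\t" + "\t".join(f"{p:.6g}" for p in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionWeightModel":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != list(BASES):
                raise ValueError(f"malformed model file {path}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(np.asarray(rows))


def train_pwm(sequences: list[str], pseudocount: float = 0.5) -> PositionWeightModel:
    """Estimate a PWM from aligned equal-length sequences."""
    if not sequences:
        raise ValueError("at least one training sequence required")
    k = len(sequences[0])
    counts = np.full((k, 4), pseudocount)
    for seq in sequences:
        if len(seq) != k:
            raise ValueError("training sequences must have equal length")
        for i, base in enumerate(seq.upper()):
            counts[i, _INDEX[base]] += 1
    return PositionWeightModel(counts)


def _model(rows: list[tuple[float, float, float, float]]) -> PositionWeightModel:
    return PositionWeightModel(np.asarray(rows))


# Donor 9-mer: positions -3..-1 exonic, +1..+6 intronic (consensus CAG|GTAAGT).
_DONOR_FREQS = [
    (0.33, 0.36, 0.19, 0.12),  # -3
    (0.61, 0.13, 0.12, 0.14),  # -2  A
    (0.10, 0.03, 0.79, 0.08),  # -1  G
    (0.01, 0.01, 0.97, 0.01),  # +1  G
    (0.01, 0.01, 0.01, 0.97),  # +2  T
    (0.55, 0.03, 0.35, 0.07),  # +3  A/g
    (0.70, 0.08, 0.12, 0.10),  # +4  A
    (0.08, 0.06, 0.80, 0.06),  # +5  G
    (0.17, 0.15, 0.19, 0.49),  # +6  t
]

# Acceptor 23-mer: 20 intronic (polypyrimidine tract ... yAG) + 3 exonic.
_PPT_COL = (0.10, 0.31, 0.12, 0.47)
_ACCEPTOR_FREQS = (
    [_PPT_COL] * 17
    + [
        (0.06, 0.31, 0.06, 0.57),  # -6..-4 stay pyrimidine-rich
        (0.97, 0.01, 0.01, 0.01),  # -2 intronic A (of the AG)
        (0.01, 0.01, 0.97, 0.01),  # -1 intronic G
        (0.28, 0.14, 0.48, 0.10),  # +1 exonic G-rich
        (0.25, 0.25, 0.25, 0.25),  # +2 exonic
        (0.25, 0.25, 0.25, 0.25),  # +3 exonic
    ]
)

# Branch heptamer: n n y U n A y with the branch adenosine at position 6.
_BRANCH_FREQS = [
    (0.25, 0.25, 0.25, 0.25),  # 1 n
    (0.25, 0.25, 0.25, 0.25),  # 2 n
    (0.08, 0.42, 0.08, 0.42),  # 3 y
    (0.04, 0.06, 0.04, 0.86),  # 4 U
    (0.40, 0.20, 0.20, 0.20),  # 5 n (slightly A-rich)
    (0.94, 0.02, 0.02, 0.02),  # 6 A (branch)
    (0.08, 0.42, 0.08, 0.42),  # 7 y
]


def default_donor_model() -> PositionWeightModel:
    return _model(_DONOR_FREQS)


def default_acceptor_model() -> PositionWeightModel:
    return _model(_ACCEPTOR_FREQS)


def default_branch_model() -> PositionWeightModel:
    return _model(_BRANCH_FREQS)
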