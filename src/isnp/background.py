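"""Markov background models (order 0 or 1) for motif scanning.

The background is estimated from the regulatory sequence universe (all
promoters and enhancers supplied to the pipeline).  For order 1 the
stationary distribution is recomputed as the left eigenvector of the
transition matrix, so the model is internally consistent even when the
training sequences are short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ALPHABET, BASE_INDEX


def stationary_from_transition(transition: np.ndarray) -> np.ndarray:
    """Left eigenvector of a row-stochastic matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class BackgroundModel:
    order: int
    stationary: np.ndarray  # (4,) probabilities, A C G T
    transition: np.ndarray = field(default=None)  # (4,4) row-stochastic

    def __post_init__(self):
        self.stationary = np.asarray(self.stationary, dtype=float)
        if self.order not in (0, 1):
            raise ValueError("background order must be 0 or 1")
        if self.order == 0 or self.transition is None:
            # order-0 chains are a special case: every row is the stationary
            self.transition = np.tile(self.stationary, (4, 1))
        self.transition = np.asarray(self.transition, dtype=float)
        if self.stationary.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("background model has wrong shape")
        if (self.stationary <= 0).any() or (self.transition < 0).any():
            # zero transition cells can arise with a zero pseudocount; the
            # scanner floors their log-probabilities
            raise ValueError("background probabilities must be positive")
        if abs(self.stationary.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")

    @classmethod
    def uniform(cls, order: int = 0) -> "BackgroundModel":
        return cls(order=order, stationary=np.full(4, 0.25))

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Generate one random sequence from the model."""
        bases = np.empty(length, dtype=int)
        if length == 0:
            return ""
        bases[0] = rng.choice(4, p=self.stationary)
        for i in range(1, length):
            bases[i] = rng.choice(4, p=self.transition[bases[i - 1]])
        return "".join(ALPHABET[b] for b in bases)


def estimate_background(sequences, order: int = 1,
                        pseudocount: float = 0.01) -> BackgroundModel:
    """Estimate a background model from mono-/di-nucleotide counts.

    ``pseudocount`` is added to every mono- and di-nucleotide count cell.
    Runs of N break dinucleotide counting.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = list(sequences)
    mono = np.full(4, pseudocount, dtype=float)
    di = np.full((4, 4), pseudocount, dtype=float)
    total = 0
    for seq in sequences:
        seq = seq.upper()
        prev = None
        for ch in seq:
            b = BASE_INDEX.get(ch)
            if b is None:
                prev = None
                continue
            mono[b] += 1
            total += 1
            if prev is not None:
                di[prev, b] += 1
            prev = b
    if total == 0:
        raise ValueError("background estimation needs at least one ACGT base")
    if order == 0:
        return BackgroundModel(order=0, stationary=mono / mono.sum())
    row_sums = di.sum(axis=1, keepdims=True)
    # contexts never observed (possible only with pseudocount 0): uniform row
    di = np.where(row_sums > 0, di, 0.25)
    transition = di / di.sum(axis=1, keepdims=True)
    return BackgroundModel(order=1, stationary=stationary_from_transition(transition),
                           transition=transition)
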