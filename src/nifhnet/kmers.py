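"""Frequency-ranked k-mer general list (GL) and binary presence vectors.

The GL is the ordered list of the ``top_n`` most frequent k-mers in the
positive (NifH) training sequences.  Any sequence is then featurised as a
binary vector whose i-th entry records whether the i-th GL k-mer occurs in
it as a substring — the order of the GL defines the feature layout, so the
list is serialised alongside any trained model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_io import ProteinRecord

__all__ = ["GeneralKmerList", "enumerate_kmers", "build_general_list", "kmer_vector"]


@dataclass(frozen=True)
class GeneralKmerList:
    """Ordered top-N k-mers with their source-dataset counts."""

    k: int
    kmers: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.kmers) != len(self.counts):
            raise ValueError("kmers and counts must align")
        if any(len(m) != self.k for m in self.kmers):
            raise ValueError(f"all k-mers must have length {self.k}")
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("k-mers must be distinct")
        if any(a < b for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing in list order")

    def __len__(self) -> int:
        return len(self.kmers)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "rank": np.arange(1, len(self) + 1),
            "kmer": list(self.kmers),
            "count": list(self.counts),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneralKmerList":
        df = pd.read_csv(path).sort_values("rank")
        kmers = tuple(df["kmer"].astype(str))
        if not kmers:
            raise ValueError(f"{path}: empty general list")
        return cls(k=len(kmers[0]), kmers=kmers, counts=tuple(int(c) for c in df["count"]))


def enumerate_kmers(sequence: str, k: int) -> list[str]:
    """All overlapping length-k substrings in positional order (with repeats).

    Returns the empty list when the sequence is shorter than k.
    """
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def build_general_list(positives: Sequence[ProteinRecord], k: int, top_n: int,
                       count_mode: str = "occurrence") -> GeneralKmerList:
    """Count k-mers across the positive sequences and keep the ``top_n`` most frequent.

    ``count_mode="occurrence"`` (default) counts every occurrence including
    within-sequence repeats; ``"presence"`` counts each sequence at most once
    per k-mer (document frequency).  Ties at equal count are broken
    lexicographically ascending so the list order is deterministic.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if count_mode not in ("occurrence", "presence"):
        raise ValueError(f"unknown count_mode {count_mode!r}")

    counter: Counter[str] = Counter()
    for rec in positives:
        kmers = enumerate_kmers(rec.sequence, k)
        counter.update(set(kmers) if count_mode == "presence" else kmers)
    if not counter:
        raise ValueError(f"no k-mers extractable: all sequences shorter than k={k}")

    ranked = sorted(counter.items(), key=lambda item: (-item[1], item[0]))[:top_n]
    return GeneralKmerList(k=k,
                           kmers=tuple(m for m, _ in ranked),
                           counts=tuple(c for _, c in ranked))


def kmer_vector(sequence: str, gl: GeneralKmerList) -> np.ndarray:
    """Binary presence vector over the GL: entry i is 1 iff ``gl.kmers[i]`` occurs
    as a substring of ``sequence``, in GL order."""
    return np.array([1 if m in sequence else 0 for m in gl.kmers], dtype=np.float32)
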