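"""Synthetic labeled protein datasets with controllable class structure.

Positives are background sequences with each configured motif written in
once at a uniform random position (optionally corrupted by per-position
substitutions); negatives are pure background.  Lengths are drawn uniformly
from the configured range, which defaults to the 50–1173 aa span of the
real NifH training data.  Everything is reproducible from the spec's seed.

These datasets emulate the *separability* structure of the real problem —
a class-discriminative subsequence on a random background — not the
phylogenetic correlation or composition biases of UniProt sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seq_io import ProteinRecord, read_fasta, write_fasta, write_csv

__all__ = ["STANDARD_AA", "SyntheticSpec", "generate_dataset", "write_fixture",
           "read_fixture"]

#: the 20 standard amino acids, used for background composition
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for a two-class synthetic dataset."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (50, 1173)
    motifs: tuple[str, ...] = ("WQCDKGH",)  # one clean 7-mer by default
    motif_mutation_rate: float = 0.0
    background: Optional[tuple[float, ...]] = None  # uniform over 20 aa if None
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.motif_mutation_rate <= 1.0:
            raise ValueError("motif_mutation_rate must be in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length_range")
        if self.n_pos and not all(self.motifs):
            raise ValueError("motifs must be non-empty strings")
        if self.background is not None and len(self.background) != len(STANDARD_AA):
            raise ValueError("background must give one weight per standard amino acid")


def _background_seq(rng: np.random.Generator, length: int, p) -> np.ndarray:
    return rng.choice(len(STANDARD_AA), size=length, p=p)


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return motif
    out = []
    for ch in motif:
        if rng.random() < rate:
            alternatives = [a for a in STANDARD_AA if a != ch]
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(ch)
    return "".join(out)


def generate_dataset(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Labeled records: ``n_pos`` positives with planted motifs, ``n_neg``
    pure-background negatives, fully reproducible from ``spec.seed``."""
    lo, hi = spec.length_range
    if spec.n_pos:
        longest = max(len(m) for m in spec.motifs)
        if longest > lo:
            raise ValueError(
                f"motif of length {longest} cannot fit the minimum sequence length {lo}")
    rng = np.random.default_rng(spec.seed)
    p = None
    if spec.background is not None:
        p = np.asarray(spec.background, dtype=float)
        p = p / p.sum()

    records: list[ProteinRecord] = []
    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = _background_seq(rng, length, p)
        chars = [STANDARD_AA[j] for j in seq]
        for motif in spec.motifs:
            planted = _mutate(motif, spec.motif_mutation_rate, rng)
            start = int(rng.integers(0, length - len(planted) + 1))
            chars[start:start + len(planted)] = list(planted)
        records.append(ProteinRecord(f"pos_{i:05d}", "".join(chars), label=1))
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = _background_seq(rng, length, p)
        records.append(ProteinRecord(
            f"neg_{i:05d}", "".join(STANDARD_AA[j] for j in seq), label=0))
    return records


def write_fixture(dataset: Sequence[ProteinRecord], path, format: str = "fasta",
                  spec: Optional[SyntheticSpec] = None) -> list[Path]:
    """Write a dataset so it round-trips losslessly through the seq_io readers.

    ``fasta`` writes one file per class (``<stem>_pos.fasta`` /
    ``<stem>_neg.fasta``); ``csv`` writes a single id,sequence,label table.
    A manifest JSON recording the generator spec is written alongside when
    ``spec`` is given.  Returns the written paths.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "fasta":
        stem = path.with_suffix("")
        for label, tag in ((1, "pos"), (0, "neg")):
            subset = [r for r in dataset if r.label == label]
            if subset:
                target = Path(f"{stem}_{tag}.fasta")
                write_fasta(subset, target)
                written.append(target)
    elif format == "csv":
        write_csv(dataset, path, with_label=True)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture format {format!r}")

    if spec is not None:
        manifest = path.with_suffix(".manifest.json")
        manifest.write_text(json.dumps({"spec": asdict(spec)}, indent=2))
        written.append(manifest)
    return written


def read_fixture(path, format: str = "fasta") -> list[ProteinRecord]:
    """Read back a fixture written by :func:`write_fixture`, labels included."""
    path = Path(path)
    if format == "fasta":
        stem = path.with_suffix("")
        records: list[ProteinRecord] = []
        for label, tag in ((1, "pos"), (0, "neg")):
            target = Path(f"{stem}_{tag}.fasta")
            if target.exists():
                records.extend(read_fasta(target, label=label))
        return records
    if format == "csv":
        import pandas as pd

        df = pd.read_csv(path, dtype={"id": str, "sequence": str})
        return [ProteinRecord(str(r.id), str(r.sequence),
                              None if pd.isna(r.label) else int(r.label))
                for r in df.itertuples()]
    raise ValueError(f"unknown fixture format {format!r}")
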