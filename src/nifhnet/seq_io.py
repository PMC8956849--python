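"""Reading, validation, filtering and redundancy reduction of protein datasets.

Sequences arrive either as FASTA (UniProt-style exports) or as simple
two-column tables (CSV with ``id,sequence`` columns, or plain text with
alternating identifier/sequence lines).  Records carry an optional binary
label: 1 for NifH (dinitrogenase reductase), 0 for non-NifH.

The accepted alphabet is the 20 standard amino acids plus the ambiguity /
rare-residue codes X, B, Z, U and O, uppercased; table readers drop rows
with other characters and log how many were dropped, while the FASTA reader
rejects them the same way.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("nifhnet")

#: 20 standard amino acids plus ambiguity codes (X, B, Z) and the rare
#: translated residues selenocysteine (U) and pyrrolysine (O).
ACCEPTED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")

__all__ = [
    "ACCEPTED_ALPHABET",
    "ProteinRecord",
    "LengthFilterSpec",
    "ClusterSpec",
    "FastaParseError",
    "read_fasta",
    "read_table",
    "write_fasta",
    "write_csv",
    "filter_by_length",
    "reduce_redundancy",
    "pairwise_identity",
]


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence, optionally labeled.

    ``label`` is 1 for NifH, 0 for non-NifH, ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self):
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        bad = set(self.sequence) - ACCEPTED_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside the accepted "
                "amino-acid alphabet")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Optional[int]) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence, label)


@dataclass(frozen=True)
class LengthFilterSpec:
    """Inclusive sequence-length bounds in amino acids."""

    min_len: int = 50
    max_len: int = 1173

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


@dataclass(frozen=True)
class ClusterSpec:
    """Redundancy-reduction settings.

    ``internal_greedy`` is the built-in dependency-free clusterer;
    ``external_cdhit`` shells out to a CD-HIT binary when one is installed.
    """

    identity_threshold: float = 0.90
    method: str = "internal_greedy"

    def __post_init__(self):
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.method not in ("internal_greedy", "external_cdhit"):
            raise ValueError(f"unknown clustering method {self.method!r}")


def _clean_sequence(raw: str) -> str:
    return "".join(raw.split()).upper()


def read_fasta(path, label: Optional[int] = None) -> list[ProteinRecord]:
    """Read a FASTA file into records, in file order.

    The id is the header token before the first whitespace; wrapped sequence
    lines are concatenated and uppercased.  Entries with characters outside
    the accepted alphabet are dropped with a logged count.  A sequence line
    before any header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header")
                break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []

    records: list[ProteinRecord] = []
    dropped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(entry.seq))
        try:
            records.append(ProteinRecord(entry.id, seq, label))
        except ValueError:
            dropped += 1
    if dropped:
        logger.warning("%s: dropped %d record(s) failing alphabet validation",
                       path, dropped)
    return records


def read_table(path, format: str = "csv", label: Optional[int] = None) -> list[ProteinRecord]:
    """Read a two-column table of (identifier, sequence) rows.

    ``format="csv"`` expects columns named ``id`` and ``sequence`` (extra
    columns are ignored; a headerless two-column CSV is also accepted).
    ``format="txt"`` expects alternating identifier / sequence lines, with an
    optional ``>`` prefix on identifiers.  Rows failing alphabet validation
    are dropped with a logged count.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, dtype=str)
        cols = {c.strip().lower(): c for c in df.columns}
        if "id" in cols and "sequence" in cols:
            pairs = zip(df[cols["id"]], df[cols["sequence"]])
        else:
            # headerless two-column file: re-read without a header row
            df = pd.read_csv(path, dtype=str, header=None)
            if df.shape[1] < 2:
                raise ValueError(f"{path}: need id,sequence columns")
            pairs = zip(df[0], df[1])
        rows = [(str(i), str(s)) for i, s in pairs]
    elif format == "txt":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if len(lines) % 2:
            raise ValueError(f"{path}: odd number of non-blank lines for txt format")
        rows = [(lines[i].lstrip(">").split()[0], lines[i + 1])
                for i in range(0, len(lines), 2)]
    else:
        raise ValueError(f"unknown table format {format!r}")

    records: list[ProteinRecord] = []
    dropped = 0
    for rid, seq in rows:
        try:
            records.append(ProteinRecord(rid, _clean_sequence(seq), label))
        except ValueError:
            dropped += 1
    if dropped:
        logger.warning("%s: dropped %d row(s) failing alphabet validation", path, dropped)
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_csv(records: Iterable[ProteinRecord], path, with_label: bool = False) -> None:
    recs = list(records)
    data = {"id": [r.id for r in recs], "sequence": [r.sequence for r in recs]}
    if with_label:
        data["label"] = [r.label for r in recs]
    pd.DataFrame(data).to_csv(path, index=False)


def filter_by_length(records: Sequence[ProteinRecord],
                     spec: LengthFilterSpec = LengthFilterSpec()) -> list[ProteinRecord]:
    """Keep records with ``min_len <= length <= max_len`` (inclusive), in order."""
    return [r for r in records if spec.min_len <= r.length <= spec.max_len]


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped head-aligned identity: matching columns / min(len_a, len_b)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return matches / n


def _greedy_cluster(records: Sequence[ProteinRecord], threshold: float) -> list[ProteinRecord]:
    # Longest-first greedy clustering in the CD-HIT spirit: a record joins the
    # first representative it matches at >= threshold identity, else founds a
    # new cluster.
    ordered = sorted(records, key=lambda r: r.length, reverse=True)
    reps: list[ProteinRecord] = []
    for rec in ordered:
        if not any(pairwise_identity(rec.sequence, rep.sequence) >= threshold
                   for rep in reps):
            reps.append(rec)
    return reps


def _cdhit_cluster(records: Sequence[ProteinRecord], threshold: float) -> list[ProteinRecord]:
    exe = shutil.which("cd-hit") or shutil.which("cdhit")
    if exe is None:
        raise RuntimeError(
            "external_cdhit requested but no cd-hit binary found on PATH; "
            "use ClusterSpec(method='internal_greedy') instead")
    by_id = {}
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        uniq = []
        for i, rec in enumerate(records):
            key = f"s{i}"
            by_id[key] = rec
            uniq.append(ProteinRecord(key, rec.sequence, rec.label))
        write_fasta(uniq, fin)
        subprocess.run([exe, "-i", str(fin), "-o", str(fout), "-c", str(threshold)],
                       check=True, capture_output=True)
        kept = read_fasta(fout)
    return [by_id[r.id] for r in kept]


def reduce_redundancy(records: Sequence[ProteinRecord],
                      spec: ClusterSpec = ClusterSpec()) -> list[ProteinRecord]:
    """Remove sequences >= ``identity_threshold`` identical to a retained one.

    Returns cluster representatives only.  The internal greedy method sorts
    by length descending and uses ungapped head-aligned identity over the
    shorter sequence; CD-HIT's full heuristic is available via
    ``method="external_cdhit"`` when the binary is installed.
    """
    if spec.method == "external_cdhit":
        return _cdhit_cluster(records, spec.identity_threshold)
    return _greedy_cluster(records, spec.identity_threshold)
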