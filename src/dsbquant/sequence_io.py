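"""Genome FASTA input and assembly-level filtering.

Sequences are normalized to the {A, C, G, T, N} alphabet: lowercase is
uppercased and every other character (IUPAC ambiguity codes included) is
masked to N.  Because all supported recognition sites are unambiguous
A/C/G/T strings, N-masking guarantees a masked position can never take
part in a match.

Mitochondrial, plastid and unplaced records are excluded by default when
building an assembly for break-count calibration, since those standards
are defined on the nuclear chromosomes only.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "GenomeAssembly",
    "DEFAULT_EXCLUDE_PATTERNS",
    "read_fasta",
    "write_fasta",
    "filter_assembly",
]

#: Header substrings excluded by default: organellar DNA and unplaced or
#: unlocalized scaffolds.  Matched case-insensitively; user-overridable.
DEFAULT_EXCLUDE_PATTERNS: tuple[str, ...] = (
    "chrM",
    "MT",
    "mito",
    "chloroplast",
    "scaffold",
    "random",
    "chrUn",
    "Un_",
)

_NON_ACGT = re.compile(r"[^ACGT]")
_INVALID = re.compile(r"[^ACGTN]")


def _normalize(seq: str) -> str:
    """Uppercase and mask every non-ACGT character to N."""
    return _NON_ACGT.sub("N", seq.upper())


@dataclass(frozen=True)
class GenomeRecord:
    """One sequence of an assembly.

    Parameters
    ----------
    id : str
        Record identifier from the FASTA header (first whitespace token).
    residues : str
        Normalized sequence over {A, C, G, T, N}.
    topology : {"linear", "circular"}
        Circular molecules (e.g. bacterial chromosomes) wrap at the
        origin for site scanning and fragment counting.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if _INVALID.search(self.residues):
            raise ValueError("residues must be normalized to A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeAssembly:
    """An ordered collection of genome records with a total size."""

    organism: str
    records: list[GenomeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r}")

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(
    path: str | Path,
    circular_ids: Iterable[str] = (),
    organism: str = "",
) -> GenomeAssembly:
    """Read a (possibly gzipped) FASTA file into a :class:`GenomeAssembly`.

    Parameters
    ----------
    path : path
        FASTA file; sequence lines may be mixed case and wrapped.
    circular_ids : iterable of str
        Record ids to flag as circular; all others are linear.
    organism : str
        Label stored on the assembly.

    Raises
    ------
    ValueError
        If the file contains no sequences or a duplicate record id.
    """
    path = Path(path)
    circ = set(circular_ids)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            topology = "circular" if rec.id in circ else "linear"
            records.append(
                GenomeRecord(rec.id, _normalize(str(rec.seq)), topology)
            )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly(organism=organism or path.stem, records=records)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    """Write an assembly as wrapped FASTA (default 60 columns)."""
    with open(path, "w") as fh:
        for rec in assembly:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def filter_assembly(
    assembly: GenomeAssembly,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
) -> GenomeAssembly:
    """Drop records whose id contains any pattern (case-insensitive).

    With an empty pattern list the assembly is returned unchanged.

    Raises
    ------
    ValueError
        If every record is excluded.
    """
    patterns = [p.lower() for p in exclude_patterns]
    kept = [
        r
        for r in assembly
        if not any(p in r.id.lower() for p in patterns)
    ]
    if not kept:
        raise ValueError("empty assembly after filtering")
    return GenomeAssembly(organism=assembly.organism, records=kept)
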