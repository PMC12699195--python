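"""Restriction-site scanning and in-silico digestion.

Site occurrences are located with the Sunday exact string-matching
algorithm (bad-character shift keyed on the text character one position
past the current window).  A naive sliding-window matcher is kept as an
independent oracle for property tests.

All bundled enzymes are blunt cutters with palindromic recognition sites,
so scanning the forward strand alone finds every double-strand site;
non-palindromic sites are rejected rather than silently under-counted.
Coordinates are 0-based half-open internally; report files use 1-based
inclusive positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .sequence_io import GenomeAssembly, GenomeRecord

__all__ = [
    "EnzymeSpec",
    "DigestOptions",
    "DigestResult",
    "BUNDLED_ENZYMES",
    "reverse_complement",
    "sunday_search",
    "naive_search",
    "count_sites",
    "digest",
    "fragment_fraction_below",
    "load_enzyme_table",
    "write_site_report",
    "write_fragment_histogram",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}."""
    upper = seq.upper()
    if any(c not in "ACGTN" for c in upper):
        raise ValueError(f"non-ACGTN character in {seq!r}")
    return upper.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A blunt-end restriction enzyme.

    Parameters
    ----------
    name : str
        Enzyme name (e.g. ``"EcoRV"``).
    site : str
        Recognition sequence over {A, C, G, T}; must equal its own
        reverse complement (blunt palindromic cutters only).
    cut_offset : int
        Cut position within the site counted from its first base,
        strictly inside the site.  Blunt cutters cut at the center.
    methylation_sensitive : bool
        True when cleavage is blocked by CpG methylation in mammals.
    """

    name: str
    site: str
    cut_offset: int
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError("recognition site must be at least 4 bp")
        if any(c not in "ACGT" for c in self.site):
            raise ValueError("ambiguous pattern unsupported")
        if not 0 < self.cut_offset < len(self.site):
            raise ValueError("cut_offset must lie strictly inside the site")

    @property
    def is_palindrome(self) -> bool:
        return self.site == reverse_complement(self.site)


#: Bundled blunt-end enzymes; cut offsets follow the blunt-center rule.
#: EheI is CpG-methylation sensitive in mammals.
BUNDLED_ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("AluI", "AGCT", 2),
        EnzymeSpec("BsuRI", "GGCC", 2),
        EnzymeSpec("DraI", "TTTAAA", 3),
        EnzymeSpec("SspI", "AATATT", 3),
        EnzymeSpec("StuI", "AGGCCT", 3),
        EnzymeSpec("EcoRV", "GATATC", 3),
        EnzymeSpec("EheI", "GGCGCC", 3, methylation_sensitive=True),
    )
}


@dataclass(frozen=True)
class DigestOptions:
    """Digestion report options.

    ``max_fragment_bp`` is the strict upper size bound used for the
    sub-threshold fragment count (2000 bp by default: the size below
    which ligation-mediated qPCR amplifies fragments efficiently, hence
    the count that defines a standard's theoretical break number).
    """

    max_fragment_bp: int = 2000

    def __post_init__(self) -> None:
        if self.max_fragment_bp <= 0:
            raise ValueError("max_fragment_bp must be positive")


@dataclass
class DigestResult:
    """Outcome of an in-silico digestion of one assembly by one enzyme."""

    enzyme: str
    site_count: int
    cut_positions: dict[str, list[int]]
    fragment_lengths: list[int]
    threshold_bp: int
    fragment_count: int = field(init=False)
    sub_threshold_count: int = field(init=False)
    sub_threshold_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.fragment_count = len(self.fragment_lengths)
        self.sub_threshold_count = sum(
            1 for L in self.fragment_lengths if L < self.threshold_bp
        )
        self.sub_threshold_fraction = (
            self.sub_threshold_count / self.fragment_count
            if self.fragment_count
            else 0.0
        )


def _check_pattern(pattern: str) -> None:
    if any(c not in "ACGT" for c in pattern):
        raise ValueError("ambiguous pattern unsupported")


def sunday_search(text: str, pattern: str) -> list[int]:
    """All (overlapping) occurrences of ``pattern`` in ``text``, Sunday scan.

    The shift after a failed or successful window comparison is taken
    from the text character just past the window: if that character does
    not occur in the pattern the window jumps a full pattern length + 1,
    otherwise it aligns the character with its last occurrence in the
    pattern.  Windows containing N never match because the pattern is
    restricted to A/C/G/T.
    """
    _check_pattern(pattern)
    m, n = len(pattern), len(text)
    if m == 0 or m > n:
        return []
    # last occurrence of each character in the pattern
    shift = {c: m - i for i, c in enumerate(pattern)}
    out: list[int] = []
    i = 0
    while i <= n - m:
        if text[i : i + m] == pattern:
            out.append(i)
        nxt = i + m
        if nxt >= n:
            break
        i += shift.get(text[nxt], m + 1)
    return out


def naive_search(text: str, pattern: str) -> list[int]:
    """Exhaustive sliding-window matcher; oracle for :func:`sunday_search`."""
    _check_pattern(pattern)
    m = len(pattern)
    if m == 0 or m > len(text):
        return []
    return [
        i for i in range(len(text) - m + 1) if text[i : i + m] == pattern
    ]


def _require_palindrome(enzyme: EnzymeSpec) -> None:
    if not enzyme.is_palindrome:
        raise ValueError(
            "non-palindromic recognition sequences require double-strand "
            "scanning (unsupported)"
        )


def _record_matches(record: GenomeRecord, site: str) -> list[int]:
    """Match start positions on one record, wrapping the origin if circular.

    For circular records the sequence is extended with its first
    ``len(site) - 1`` residues so occurrences spanning the origin are
    found; only starts within the original length are reported.
    """
    m = len(site)
    if record.topology == "circular" and len(record) >= m:
        text = record.residues + record.residues[: m - 1]
        return [p for p in sunday_search(text, site) if p < len(record)]
    return sunday_search(record.residues, site)


def count_sites(assembly: GenomeAssembly, enzyme: EnzymeSpec) -> int:
    """Total recognition-site occurrences over all records (forward strand)."""
    _require_palindrome(enzyme)
    return sum(len(_record_matches(r, enzyme.site)) for r in assembly)


def _fragments_linear(length: int, cuts: list[int]) -> list[int]:
    if not cuts:
        return [length]
    edges = [0] + cuts + [length]
    return [b - a for a, b in zip(edges, edges[1:])]


def _fragments_circular(length: int, cuts: list[int]) -> list[int]:
    if not cuts:
        return [length]
    if len(cuts) == 1:
        return [length]
    frags = [b - a for a, b in zip(cuts, cuts[1:])]
    frags.append(length - cuts[-1] + cuts[0])
    return frags


def digest(
    assembly: GenomeAssembly,
    enzyme: EnzymeSpec,
    options: DigestOptions = DigestOptions(),
) -> DigestResult:
    """In-silico digestion: cut positions, fragment lengths and size stats.

    A site starting at position ``p`` cuts at ``p + cut_offset``
    (modulo the record length on circular molecules).  Overlapping sites
    are all counted as occurrences, but coincident cut coordinates
    collapse to a single cut — two recognition events at one coordinate
    produce one break.
    """
    _require_palindrome(enzyme)
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    site_count = 0
    cut_positions: dict[str, list[int]] = {}
    fragment_lengths: list[int] = []
    for rec in assembly:
        matches = _record_matches(rec, enzyme.site)
        site_count += len(matches)
        L = len(rec)
        if rec.topology == "circular":
            cuts = sorted({(p + enzyme.cut_offset) % L for p in matches})
            fragment_lengths.extend(_fragments_circular(L, cuts))
        else:
            cuts = sorted({p + enzyme.cut_offset for p in matches})
            fragment_lengths.extend(_fragments_linear(L, cuts))
        cut_positions[rec.id] = cuts
    return DigestResult(
        enzyme=enzyme.name,
        site_count=site_count,
        cut_positions=cut_positions,
        fragment_lengths=fragment_lengths,
        threshold_bp=options.max_fragment_bp,
    )


def fragment_fraction_below(
    result: DigestResult, threshold_bp: int
) -> tuple[int, float]:
    """Count and fraction of fragments strictly shorter than ``threshold_bp``."""
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")
    if result.fragment_count == 0:
        raise ValueError("digest produced no fragments")
    count = sum(1 for L in result.fragment_lengths if L < threshold_bp)
    return count, count / result.fragment_count


def load_enzyme_table(path: str | Path) -> dict[str, EnzymeSpec]:
    """Read an enzyme table (TSV or JSON).

    TSV columns: name, site, cut_offset, methylation_sensitive.
    JSON: a list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
    out = {}
    for row in rows:
        spec = EnzymeSpec(
            name=str(row["name"]),
            site=str(row["site"]).upper(),
            cut_offset=int(row["cut_offset"]),
            methylation_sensitive=_as_bool(row.get("methylation_sensitive", False)),
        )
        out[spec.name] = spec
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def write_site_report(
    assembly: GenomeAssembly, enzyme: EnzymeSpec, path: str | Path
) -> pd.DataFrame:
    """Write a per-site TSV (record, position_1based, enzyme)."""
    _require_palindrome(enzyme)
    rows = [
        {"record": rec.id, "position_1based": p + 1, "enzyme": enzyme.name}
        for rec in assembly
        for p in _record_matches(rec, enzyme.site)
    ]
    df = pd.DataFrame(rows, columns=["record", "position_1based", "enzyme"])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_fragment_histogram(
    result: DigestResult, path: str | Path, bin_bp: int = 500
) -> pd.DataFrame:
    """Write a fragment-length histogram TSV (length_bin, count).

    Bins are half-open ``[k*bin_bp, (k+1)*bin_bp)`` labelled by their
    lower edge.
    """
    bins: dict[int, int] = {}
    for L in result.fragment_lengths:
        edge = (L // bin_bp) * bin_bp
        bins[edge] = bins.get(edge, 0) + 1
    df = pd.DataFrame(
        sorted(bins.items()), columns=["length_bin", "count"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
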