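"""Seeded synthetic data: random genomes, planted-site genomes, Ct tables.

Everything here is reproducible from a single integer seed per call; no
hidden global random state.  Genomes are i.i.d. residue draws at a given
GC content.  ``plant_sites`` builds digestion truth sets: a background
scrubbed of accidental recognition sites with exactly ``k`` copies of
the site written in, verified by exhaustive search.  ``simulate_ct``
emulates qPCR measurement of standards from a known calibration line
with Gaussian Ct noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scanner import EnzymeSpec, naive_search
from .sequence_io import GenomeRecord

__all__ = [
    "GenomeSimSpec",
    "CtSimSpec",
    "generate_genome",
    "plant_sites",
    "simulate_ct",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSimSpec:
    """Random-genome parameters: length, GC content, seed, topology."""

    length_bp: int
    gc_fraction: float = 0.5
    seed: int = 0
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _draw(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    return rng.choice(_BASES, size=n, p=p)


def generate_genome(spec: GenomeSimSpec, record_id: str = "sim") -> GenomeRecord:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng(spec.seed)
    seq = "".join(_draw(rng, spec.length_bp, spec.gc_fraction))
    return GenomeRecord(id=record_id, residues=seq, topology=spec.topology)


def _scan_text(record_seq: str, site: str, circular: bool) -> list[int]:
    m = len(site)
    text = record_seq + record_seq[: m - 1] if circular else record_seq
    hits = naive_search(text, site)
    if circular:
        hits = [p for p in hits if p < len(record_seq)]
    return hits


def plant_sites(
    background: GenomeSimSpec,
    enzyme: EnzymeSpec,
    k: int,
    min_gap_bp: int = 50,
    max_attempts: int = 1000,
) -> GenomeRecord:
    """A genome containing the enzyme's site exactly ``k`` times.

    The random background is scrubbed of accidental occurrences by
    resampling the offending windows, then the site is written in at
    ``k`` positions at least ``min_gap_bp`` apart.  The result is
    post-verified by exhaustive search; failure to reach exactly ``k``
    occurrences within ``max_attempts`` raises.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    m = len(enzyme.site)
    if k * (m + min_gap_bp) > background.length_bp:
        raise ValueError("genome too short for k sites with the given gap")
    rng = np.random.default_rng(background.seed)
    circular = background.topology == "circular"
    for _ in range(max_attempts):
        seq = _draw(rng, background.length_bp, background.gc_fraction)
        # scrub accidental sites by resampling their windows
        for _ in range(max_attempts):
            hits = _scan_text("".join(seq), enzyme.site, circular)
            if not hits:
                break
            for p in hits:
                idx = [(p + j) % background.length_bp for j in range(m)]
                seq[idx] = _draw(rng, m, background.gc_fraction)
        else:
            continue
        if k > 0:
            positions = _spaced_positions(
                rng, background.length_bp, k, m, min_gap_bp, circular
            )
            for p in positions:
                for j, c in enumerate(enzyme.site):
                    seq[(p + j) % background.length_bp] = c
        record = GenomeRecord(
            id=f"planted-{enzyme.name}-k{k}",
            residues="".join(seq),
            topology=background.topology,
        )
        if len(_scan_text(record.residues, enzyme.site, circular)) == k:
            return record
    raise RuntimeError(
        f"could not build a genome with exactly {k} sites in "
        f"{max_attempts} attempts"
    )


def _spaced_positions(
    rng: np.random.Generator,
    length: int,
    k: int,
    site_len: int,
    min_gap: int,
    circular: bool,
) -> list[int]:
    """k start positions, pairwise >= site_len + min_gap apart."""
    span = site_len + min_gap
    # place on an evenly divided backbone with random jitter inside slots
    usable = length if circular else length - site_len
    slot = usable // k
    if slot < span:
        raise ValueError("genome too short for the requested spacing")
    jitter = rng.integers(0, slot - span + 1, size=k)
    return [int(i * slot + jitter[i]) for i in range(k)]


@dataclass(frozen=True)
class CtSimSpec:
    """Simulated-measurement parameters for a known calibration line."""

    intercept_a: float
    slope_b: float
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_ct(
    points_n: Sequence[float],
    spec: CtSimSpec,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulated Ct table for standards with known break numbers.

    Each replicate draws ct = a - |b|*lg10(N) + Normal(0, noise_sd).
    Returns the standard Ct CSV dialect: columns sample,
    enzyme_or_condition, replicate, ct.
    """
    n_vals = np.asarray(points_n, dtype=float)
    if np.any(n_vals <= 0):
        raise ValueError("all N values must be positive")
    if labels is None:
        labels = [f"std{i + 1}" for i in range(len(n_vals))]
    if len(labels) != len(n_vals):
        raise ValueError("labels and points_n lengths differ")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, n in zip(labels, n_vals):
        true_ct = spec.intercept_a - abs(spec.slope_b) * np.log10(n)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.replicates)
        for rep in range(spec.replicates):
            rows.append(
                {
                    "sample": label,
                    "enzyme_or_condition": label,
                    "replicate": rep + 1,
                    "ct": true_ct + noise[rep],
                }
            )
    return pd.DataFrame(rows)
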