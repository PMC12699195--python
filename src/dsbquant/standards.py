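"""Theoretical break numbers of digestion standards.

A standard is genomic DNA fully digested by one blunt-end enzyme, so its
true number of double-strand breaks is known: the genome copy number in
the reaction times the per-genome break count.  Copy number follows from
the DNA mass, the genome size and the average mass of a base pair
(650 g/mol); the per-organism multipliers bundled here fold the reaction
mass into a single coefficient so that N_DSBs = coefficient x count.

The count that enters a standard's N_DSBs is the number of fragments
shorter than the amplification size limit (2000 bp by default), because
only those fragments amplify efficiently in ligation-mediated qPCR.  The
raw site count can be substituted explicitly for sensitivity analysis.

CpG-methylation-sensitive enzymes (EheI) under-cut mammalian DNA, so
their standards are flagged excluded for mammalian organisms.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .scanner import BUNDLED_ENZYMES, DigestOptions, DigestResult

__all__ = [
    "AVOGADRO",
    "BP_MASS_G_PER_MOL",
    "CopyNumberParams",
    "OrganismProfile",
    "StandardPoint",
    "BUNDLED_PROFILES",
    "copy_number",
    "theoretical_ndsb",
    "build_standard_table",
    "load_profile",
    "write_standard_table",
]

#: Avogadro constant as used throughout the copy-number arithmetic here
#: (6.023e23/mol, the rounded convention of the source protocol), kept
#: configurable on CopyNumberParams.
AVOGADRO = 6.023e23
#: Average molar mass of one base pair of double-stranded DNA.
BP_MASS_G_PER_MOL = 650.0


@dataclass(frozen=True)
class CopyNumberParams:
    """Inputs of the genome copy-number formula.

    copies = mass_ug * avogadro / (genome_bp * 1e6 * bp_mass)

    (the 1e6 converts micrograms to grams... times the per-bp molar mass
    gives the genome molar mass in g/mol).
    """

    mass_ug: float
    genome_bp: int
    avogadro: float = AVOGADRO
    bp_mass: float = BP_MASS_G_PER_MOL

    def __post_init__(self) -> None:
        if self.genome_bp <= 0:
            raise ValueError("genome_bp must be positive")
        if self.mass_ug < 0:
            raise ValueError("mass_ug must be non-negative")


def copy_number(params: CopyNumberParams) -> float:
    """Number of genome copies in ``mass_ug`` micrograms of DNA."""
    return params.mass_ug * params.avogadro / (
        params.genome_bp * 1e6 * params.bp_mass
    )


def theoretical_ndsb(copies: float, count: int | float) -> float:
    """Theoretical break number of a standard: copies x per-genome count.

    ``count`` is the sub-threshold fragment count for standard-curve
    construction; callers wanting the raw site count pass it explicitly.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if count < 0:
        raise ValueError("count must be non-negative")
    return copies * count


@dataclass(frozen=True)
class OrganismProfile:
    """Per-organism calibration constants.

    ``coefficient`` is the copies-per-reaction multiplier: a standard's
    N_DSBs equals coefficient x per-genome count.  ``mammalian`` gates
    the CpG-methylation exclusion rule; ``circular_chromosome`` marks
    organisms whose chromosome wraps (bacteria).
    """

    organism: str
    coefficient: float
    mammalian: bool = False
    circular_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")


#: Authoritative coefficients for the five validated organisms.
BUNDLED_PROFILES: dict[str, OrganismProfile] = {
    p.organism: p
    for p in (
        OrganismProfile("human", 1.477, mammalian=True),
        OrganismProfile("mouse", 1.773, mammalian=True),
        OrganismProfile("arabidopsis", 38.88),
        OrganismProfile("yeast", 761.7),
        OrganismProfile("ecoli", 1782.0, circular_chromosome=True),
    )
}


@dataclass
class StandardPoint:
    """One standard on a calibration curve."""

    enzyme: str
    n_dsbs: float
    ct: float
    included: bool = True


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def build_standard_table(
    digests: Sequence[DigestResult],
    profile: OrganismProfile,
    ct_table: Mapping[str, Sequence[float]],
    options: DigestOptions = DigestOptions(),
) -> list[StandardPoint]:
    """Assemble calibration standards from digests and measured Ct values.

    Parameters
    ----------
    digests : sequence of DigestResult
        One digestion per enzyme.
    profile : OrganismProfile
        Supplies the N_DSBs coefficient and the mammalian flag.
    ct_table : mapping enzyme name -> replicate Ct values
        Replicates are combined by arithmetic mean.
    options : DigestOptions
        Size threshold the digests were computed with (informational).

    Returns
    -------
    list of StandardPoint
        One point per digest, ``included=False`` for
        methylation-sensitive enzymes on mammalian profiles and for
        standards with zero sub-threshold fragments (lg undefined).
    """
    points: list[StandardPoint] = []
    for dig in digests:
        if dig.enzyme not in ct_table:
            raise ValueError(f"no Ct measurements for enzyme {dig.enzyme!r}")
        reps = list(ct_table[dig.enzyme])
        if not reps:
            raise ValueError(f"no Ct measurements for enzyme {dig.enzyme!r}")
        n_dsbs = theoretical_ndsb(profile.coefficient, dig.sub_threshold_count)
        included = True
        spec = BUNDLED_ENZYMES.get(dig.enzyme)
        if (
            profile.mammalian
            and spec is not None
            and spec.methylation_sensitive
        ):
            included = False
        if dig.sub_threshold_count == 0:
            warnings.warn(
                f"{dig.enzyme}: zero sub-threshold fragments; "
                "point excluded (lg undefined)",
                stacklevel=2,
            )
            included = False
        points.append(
            StandardPoint(
                enzyme=dig.enzyme,
                n_dsbs=n_dsbs,
                ct=_mean(reps),
                included=included,
            )
        )
    return points


def load_profile(path: str | Path) -> OrganismProfile:
    """Read an organism profile from JSON."""
    data = json.loads(Path(path).read_text())
    return OrganismProfile(
        organism=data["organism"],
        coefficient=float(data["coefficient"]),
        mammalian=bool(data.get("mammalian", False)),
        circular_chromosome=bool(data.get("circular_chromosome", False)),
    )


def write_standard_table(
    points: Sequence[StandardPoint],
    path: str | Path,
    digests: Sequence[DigestResult] = (),
) -> pd.DataFrame:
    """Write a standards TSV (enzyme, site_count, sub_threshold_count,
    n_dsbs, ct, included); digestion columns are blank when digests are
    not supplied."""
    by_enzyme = {d.enzyme: d for d in digests}
    rows = []
    for pt in points:
        dig = by_enzyme.get(pt.enzyme)
        rows.append(
            {
                "enzyme": pt.enzyme,
                "site_count": dig.site_count if dig else math.nan,
                "sub_threshold_count": dig.sub_threshold_count
                if dig
                else math.nan,
                "n_dsbs": pt.n_dsbs,
                "ct": pt.ct,
                "included": pt.included,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
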