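"""Reference calibration dataset for five model organisms.

The validated blunt-end digestion standards: theoretical double-strand
break numbers per enzyme (copy-number coefficient already applied) and
the measured LM-qPCR Ct values, for human, mouse, *Arabidopsis
thaliana*, *Saccharomyces cerevisiae* and *Escherichia coli*.  These are
the reference inputs for standard-curve fitting and regression tests;
the EheI standards of the two mammals are excluded from curve fitting
because EheI is CpG-methylation sensitive.
"""

from __future__ import annotations

from .standards import BUNDLED_PROFILES, StandardPoint

__all__ = [
    "ENZYME_ORDER",
    "THEORETICAL_NDSBS",
    "MEASURED_CT",
    "ORGANISMS",
    "reference_standards",
]

ENZYME_ORDER = ("AluI", "BsuRI", "DraI", "SspI", "StuI", "EcoRV", "EheI")

#: Theoretical N_DSBs of each organism's standards, per enzyme.
THEORETICAL_NDSBS: dict[str, tuple[int, ...]] = {
    "human": (37_817_821, 24_554_816, 8_910_629, 5_654_455, 1_500_820, 396_760, 208_617),
    "mouse": (43_178_529, 23_244_558, 7_369_625, 4_028_286, 1_112_607, 479_758, 63_204),
    "arabidopsis": (37_562_901, 8_167_522, 9_344_652, 7_827_944, 148_599, 1_038_329, 22_395),
    "yeast": (30_195_311, 13_964_246, 5_479_670, 7_428_098, 239_174, 1_649_081, 115_778),
    "ecoli": (26_227_476, 24_682_482, 1_958_418, 2_740_716, 306_504, 2_544_696, 90_882),
}

#: Measured Ct of each organism's standards, per enzyme (replicate means).
MEASURED_CT: dict[str, tuple[float, ...]] = {
    "human": (12.302, 12.726, 15.026, 16.155, 17.109, 19.460, 20.534),
    "mouse": (12.382, 13.324, 14.604, 15.965, 17.376, 18.732, 20.928),
    "arabidopsis": (12.006, 14.835, 14.617, 15.456, 19.980, 18.519, 22.202),
    "yeast": (11.213, 12.469, 14.098, 13.396, 17.998, 15.271, 19.125),
    "ecoli": (10.313, 10.515, 14.851, 14.018, 17.293, 14.199, 19.368),
}

ORGANISMS = tuple(THEORETICAL_NDSBS)


def reference_standards(organism: str) -> list[StandardPoint]:
    """Standards of one organism as :class:`StandardPoint` objects.

    EheI is flagged excluded for the mammalian organisms (human, mouse)
    per the CpG-methylation rule; all seven enzymes are included for the
    plant, yeast and bacterial standards.
    """
    if organism not in THEORETICAL_NDSBS:
        raise KeyError(f"unknown organism {organism!r}; have {ORGANISMS}")
    mammalian = BUNDLED_PROFILES[organism].mammalian
    points = []
    for enzyme, n, ct in zip(
        ENZYME_ORDER, THEORETICAL_NDSBS[organism], MEASURED_CT[organism]
    ):
        included = not (mammalian and enzyme == "EheI")
        points.append(
            StandardPoint(enzyme=enzyme, n_dsbs=float(n), ct=ct, included=included)
        )
    return points
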