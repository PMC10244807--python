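"""Molecular counting: converting localization (detection) counts into
protein copy numbers.

A detected spot count overestimates molecules because each fluorophore
blinks (mean on-events/molecule = overcounting factor, 1/p of the
geometric model) and underestimates them because only a fraction of tags
is fluorescent.  An expression scale converts tagged-protein copies into
the biological population of interest (e.g. total = 1.9x endogenous when
the tagged protein is expressed at 0.9x the endogenous level).

copies = detections / overcount / fluorescent_fraction * expression_scale

Channel presets: mEos3.2 — overcount 1.4, fluorescent fraction 0.60;
HMSiR-Halo — overcount 2.7, labeling efficiency 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CountingFactors",
    "MEOS32_FACTORS",
    "HMSIR_FACTORS",
    "copies_per_island",
    "copies_per_cell",
    "expression_ratio_from_spot_densities",
]


@dataclass(frozen=True)
class CountingFactors:
    """Correction factors for molecular counting.

    overcount: mean on-events (detections) per molecule;
    fluorescent_fraction: fraction of tags that are fluorescent/labeled;
    expression_scale: multiplicative conversion from tagged copies to the
    reported population; view_fraction: fraction of the relevant membrane
    captured in the view field; recruitment_fraction: fraction of expressed
    molecules recruited to that membrane.
    """

    overcount: float
    fluorescent_fraction: float
    expression_scale: float = 1.0
    view_fraction: float = 1.0
    recruitment_fraction: float = 1.0

    def __post_init__(self):
        if min(self.overcount, self.fluorescent_fraction,
               self.expression_scale, self.view_fraction,
               self.recruitment_fraction) <= 0:
            raise ValueError("all factors must be > 0")
        if self.fluorescent_fraction > 1:
            raise ValueError("fluorescent_fraction must be <= 1")


MEOS32_FACTORS = CountingFactors(overcount=1.4, fluorescent_fraction=0.60)
HMSIR_FACTORS = CountingFactors(overcount=2.7, fluorescent_fraction=0.90)


def copies_per_island(detections_per_island: float,
                      f: CountingFactors) -> float:
    """Copy number in one island from its detection count.

    copies = detections / overcount / fluorescent_fraction
             * expression_scale.

    The median detections/island is the recommended input — the mean is
    dominated by unresolved merged islands.
    """
    if detections_per_island < 0:
        raise ValueError("detections must be >= 0")
    return (detections_per_island / f.overcount / f.fluorescent_fraction
            * f.expression_scale)


def copies_per_cell(total_detections: float, f: CountingFactors) -> float:
    """Expressed copies per cell from the total detection count of a view
    field covering ``view_fraction`` of the membrane, of which
    ``recruitment_fraction`` of expressed molecules are present:

    copies = detections / view_fraction / recruitment_fraction
             / overcount / fluorescent_fraction.
    """
    if not (0 < f.view_fraction <= 1 and 0 < f.recruitment_fraction <= 1):
        raise ValueError("view/recruitment fractions must be in (0, 1]")
    return (total_detections / f.view_fraction / f.recruitment_fraction
            / f.overcount / f.fluorescent_fraction)


def expression_ratio_from_spot_densities(density_ratio: float,
                                         factorsA: CountingFactors,
                                         factorsB: CountingFactors
                                         ) -> float:
    """Copy-number ratio A:B (normalized to B = 1) from the ratio of
    detected spot densities, correcting each channel for overcounting and
    fluorescent fraction."""
    if density_ratio <= 0:
        raise ValueError("density ratio must be > 0")
    a = density_ratio / factorsA.overcount / factorsA.fluorescent_fraction
    b = 1.0 / factorsB.overcount / factorsB.fluorescent_fraction
    return a / b
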