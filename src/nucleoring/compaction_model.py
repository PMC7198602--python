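"""Linear compaction arithmetic for looped rDNA chromatin.

Relates the DNA contour length of the UBF-bound region of an active rRNA
gene (defaults: 15 kb at 0.33 nm per nucleotide, i.e. ~5 µm of B-form DNA)
to the circumference of the measured ring-shaped focus it folds into.  The
compaction factor is the ratio of the two; inverting the identity at an
assumed compaction range yields how many gene-sized units fit on one loop.
All outputs are exact, unrounded floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DEFAULT_REGION_BP = 15_000
DEFAULT_NM_PER_NT = 0.33


@dataclass(frozen=True)
class CompactionInput:
    """Inputs of the compaction calculation (all strictly positive)."""

    ring_diameter: float  # nm
    region_bp: float = DEFAULT_REGION_BP
    nm_per_nt: float = DEFAULT_NM_PER_NT

    def __post_init__(self) -> None:
        if min(self.ring_diameter, self.region_bp, self.nm_per_nt) <= 0:
            raise ValueError("all compaction inputs must be strictly positive")


@dataclass(frozen=True)
class CompactionResult:
    contour_nm: float
    circumference_nm: float
    compaction_factor: float
    genes_per_loop_estimate: tuple[float, float]


def contour_length(region_bp: float, nm_per_nt: float = DEFAULT_NM_PER_NT) -> float:
    """Extended DNA length of a region, nm (product, exact)."""
    if region_bp <= 0 or nm_per_nt <= 0:
        raise ValueError("region_bp and nm_per_nt must be > 0")
    return float(region_bp) * float(nm_per_nt)


def circumference(diameter: float) -> float:
    """Circumference of a circular loop of given diameter, nm."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * float(diameter)


def compaction_factor(contour_nm: float, circumference_nm: float) -> float:
    """Fold linear compaction: contour length / loop circumference."""
    if contour_nm <= 0 or circumference_nm <= 0:
        raise ValueError("lengths must be > 0")
    return float(contour_nm) / float(circumference_nm)


def genes_per_loop(
    ring_diameter: float,
    gene_unit_bp: float = DEFAULT_REGION_BP,
    compaction_range: tuple[float, float] = (6.0, 7.0),
    nm_per_nt: float = DEFAULT_NM_PER_NT,
) -> tuple[float, float]:
    """Gene-sized units per loop at the interval ends of an assumed compaction.

    genes = (pi * diameter * compaction) / (gene_unit_bp * nm_per_nt),
    evaluated at both ends of ``compaction_range``; returned unrounded.
    """
    lo, hi = compaction_range
    if not (0 < lo <= hi):
        raise ValueError("compaction_range must be a positive ordered interval")
    unit_nm = contour_length(gene_unit_bp, nm_per_nt)
    circ = circumference(ring_diameter)
    return (circ * lo / unit_nm, circ * hi / unit_nm)


def compaction_summary(inp: CompactionInput, compaction_range=(6.0, 7.0)) -> CompactionResult:
    """The full arithmetic for one measured ring diameter."""
    contour = contour_length(inp.region_bp, inp.nm_per_nt)
    circ = circumference(inp.ring_diameter)
    return CompactionResult(
        contour_nm=contour,
        circumference_nm=circ,
        compaction_factor=compaction_factor(contour, circ),
        genes_per_loop_estimate=genes_per_loop(
            inp.ring_diameter, inp.region_bp, compaction_range, inp.nm_per_nt
        ),
    )
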