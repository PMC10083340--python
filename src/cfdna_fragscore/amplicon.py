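"""Size-dependent PCR detectability of cfDNA fragments.

A fragment can template a PCR product only if it fully spans the amplicon
interval.  Under the assumption that fragmentation breakpoints fall
uniformly at random along the genome, the probability that a fragment of
length ``L`` overlapping a fixed ``A``-bp amplicon window actually contains
the whole window has the closed form ``max(0, L - A + 1) / L``.  This module
provides that containment model, a brute-force fragmentation simulator kept
as its independent oracle, and the conversion from input DNA mass to the
expected number of amplifiable target copies in a reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HAPLOID_GENOME_MASS_NG

__all__ = [
    "AmpliconAssay",
    "containment_probability",
    "simulate_containment_fraction",
    "expected_amplifiable_copies",
    "DEFAULT_ASSAYS",
]


@dataclass(frozen=True)
class AmpliconAssay:
    """A named PCR amplicon with its genomic copy number and dye label.

    Parameters
    ----------
    name : str
        Assay identifier, e.g. ``"short_106"`` or ``"OCR1_long"``.
    amplicon_length : int
        Length of the PCR product in base pairs.
    copies_per_haploid_genome : int
        Number of annealing sites per haploid genome (1 for single-copy
        targets; ~25 for the multicopy lncRNA target).
    dye : str
        Reporter fluorophore, ``"FAM"`` or ``"HEX"``.
    region_label : str
        One of ``"OCR1"``, ``"OCR2"``, ``"CCR"``, ``"multicopy"``.
    """

    name: str
    amplicon_length: int
    copies_per_haploid_genome: int = 1
    dye: str = "FAM"
    region_label: str = "multicopy"

    def __post_init__(self) -> None:
        if self.amplicon_length < 1:
            raise ValueError(f"amplicon_length must be >= 1, got {self.amplicon_length}")
        if self.copies_per_haploid_genome < 1:
            raise ValueError(
                f"copies_per_haploid_genome must be >= 1, got {self.copies_per_haploid_genome}"
            )


def containment_probability(fragment_length, amplicon_length):
    """Probability that a fragment fully contains an amplicon window.

    Under uniform random placement of fragmentation breakpoints, a fragment
    of length ``L`` that covers the amplicon start contains the whole
    ``A``-bp window with probability ``max(0, L - A + 1) / L``: of the ``L``
    equally likely phases of the fragment grid relative to the window,
    exactly ``L - A + 1`` leave the window uncut.

    Accepts scalars or arrays (broadcast). Returns 0 when ``L < A`` and
    tends to 1 as ``L/A`` grows.
    """
    L = np.asarray(fragment_length, dtype=float)
    A = np.asarray(amplicon_length, dtype=float)
    if np.any(L < 1) or np.any(A < 1):
        raise ValueError("fragment and amplicon lengths must be >= 1 bp")
    p = np.maximum(0.0, L - A + 1.0) / L
    if np.isscalar(fragment_length) and np.isscalar(amplicon_length):
        return float(p)
    return p


def simulate_containment_fraction(
    fragment_length: int,
    amplicon_length: int,
    n_trials: int = 100_000,
    seed: int = 0,
) -> float:
    """Brute-force oracle for :func:`containment_probability`.

    Fragments an (implicitly infinite) molecule into consecutive pieces of
    length ``L`` with a uniformly random grid phase, and counts the trials
    in which a fixed ``A``-bp window falls entirely inside one piece.  Kept
    deliberately independent of the closed form it checks.
    """
    if fragment_length < 1 or amplicon_length < 1:
        raise ValueError("lengths must be >= 1 bp")
    rng = np.random.default_rng(seed)
    L = int(fragment_length)
    # Integer phase of the cut grid relative to the window start.
    phase = rng.integers(0, L, size=n_trials)
    # Window occupies offsets [phase, phase + A - 1]; contained iff both
    # ends land in the same L-bp piece.
    first_piece = phase // L
    last_piece = (phase + amplicon_length - 1) // L
    return float(np.mean(first_piece == last_piece))


def expected_amplifiable_copies(pop, assay: AmpliconAssay, input_mass_ng: float) -> float:
    """Expected number of amplifiable target copies in ``input_mass_ng``.

    Combines the mass-to-genome conversion (3.3 pg per haploid genome), the
    assay's genomic copy number, and the mean containment probability over
    the sample's empirical fragment-length distribution::

        copies = (mass / 0.0033 ng) * copies_per_haploid_genome
                 * mean_L[ containment(L, A) ]

    Parameters
    ----------
    pop : FragmentPopulation
        Sample fragment lengths (the empirical length distribution).
    assay : AmpliconAssay
    input_mass_ng : float
        DNA mass loaded into the reaction, in nanograms.
    """
    lengths = np.asarray(pop.lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("population is empty")
    if input_mass_ng < 0:
        raise ValueError("input_mass_ng must be non-negative")
    genome_equivalents = input_mass_ng / HAPLOID_GENOME_MASS_NG
    mean_containment = float(np.mean(containment_probability(lengths, assay.amplicon_length)))
    return genome_equivalents * assay.copies_per_haploid_genome * mean_containment


def _region_assays(region: str, short_bp: int = 70, long_bp: int = 160) -> list[AmpliconAssay]:
    # Designed short/long product lengths for the ddPCR regions are config
    # values; 70 / 160 bp are placeholder defaults consistent with the
    # "short < 80 bp, long > 150 bp" design rule.
    return [
        AmpliconAssay(f"{region}_short", short_bp, 1, "FAM", region),
        AmpliconAssay(f"{region}_long", long_bp, 1, "HEX", region),
    ]


#: Default assay panel: per-region ddPCR short/long pairs plus the
#: multicopy qPCR pair (106 / 612 bp, ~25 annealing sites per haploid
#: genome).
DEFAULT_ASSAYS: dict[str, AmpliconAssay] = {
    a.name: a
    for a in (
        *_region_assays("OCR1"),
        *_region_assays("OCR2"),
        *_region_assays("CCR"),
        AmpliconAssay("short_106", 106, 25, "FAM", "multicopy"),
        AmpliconAssay("long_612", 612, 25, "HEX", "multicopy"),
    )
}
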