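"""Physical and instrument constants shared across modules.

All mass/copy conversions in this package go through the haploid genome
mass constant: 3.3 pg per haploid human genome, i.e. 1 ng of genomic DNA
contains ~303 haploid genome equivalents.
"""

#: Mass of one haploid human genome, in nanograms (3.3 pg).
HAPLOID_GENOME_MASS_NG: float = 0.0033

#: Haploid genome copies per nanogram of human genomic DNA (~303).
COPIES_PER_NG: float = 1.0 / HAPLOID_GENOME_MASS_NG

#: Droplet volume of the QX200-style droplet generator, in nanoliters.
DROPLET_VOLUME_NL: float = 0.85

#: Default ddPCR reaction volume, in microliters.
REACTION_VOLUME_UL: float = 20.0

#: qPCR cycle count; Cq at or beyond this is treated as a non-detect.
MAX_QPCR_CYCLES: float = 40.0

#: Average molar mass of one double-stranded base pair, g/mol.
BP_MASS_G_PER_MOL: float = 650.0
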