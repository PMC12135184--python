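"""Physical constants shared across the package.

Every nm<->bp conversion in the package goes through :data:`NM_PER_BP`
(single definition site).
"""

#: DNA rise per base pair, nm.
NM_PER_BP = 0.34

#: Reference nucleosome core DNA length, bp (crystal-structure core fit).
CORE_BP = 146

#: Mesoscale linker-DNA bead spacing, nm.
BEAD_SPACING_NM = 3.0

#: DNA base pairs represented by one linker bead (3.0 nm / 0.34 nm per bp).
BP_PER_BEAD = BEAD_SPACING_NM / NM_PER_BP  # = 8.8235...

#: Nucleosome disk radius, nm; contacts are scored below twice this value.
DISK_RADIUS_NM = 5.5

#: Default centroid-distance threshold for a nucleosome contact, nm.
CONTACT_NM = 11.0

#: Default terminal-to-terminal distance confirming a trans contact, nm.
TRANS_NM = 28.0

#: Default air/water boundary exclusion distance, nm.
BOUNDARY_NM = 5.0

#: Default thresholds for stacked-nucleosome detection.
STACK_PARA_DEG = 25.0
STACK_N_NM = 8.0

#: Default paired-linker-bead distance below which a stem is scored, nm.
STEM_NM = 2.5

#: DNA helical repeat used for linker twist register, bp per turn.
HELICAL_REPEAT_BP = 10.5


def nm_to_bp(nm: float) -> float:
    """Convert a length in nanometers to base pairs."""
    return nm / NM_PER_BP


def bp_to_nm(bp: float) -> float:
    """Convert a length in base pairs to nanometers."""
    return bp * NM_PER_BP
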