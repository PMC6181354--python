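"""Published reference coordinates and residue sets for BAF250a (ARID1A).

All positions are 1-based UniProt coordinates on ARID1A_HUMAN.  Two boundary
conventions ship for each domain: the hydrophobic-cluster (SEG-HCA) regions
and the Pfam annotations.  The residue sets are compiled from published
structural and mutational studies of the BAF250a ARID and BAF250_C domains;
the somatic-mutation list is a reconstructed subset of COSMIC missense
records restricted to the two domains (alt alleles are placeholders — only
positions matter for domain mapping and set intersections).
"""

from __future__ import annotations

from .mutmap import DomainRegion
from .seq_io import MutationRecord
from .surface import ResidueSet

#: Foldable regions of BAF250a by hydrophobic-cluster segmentation.
SEGHCA_REGIONS = [
    DomainRegion(name="region2", start=781, end=908),
    DomainRegion(name="ARID", start=1008, end=1107),
    DomainRegion(name="region8", start=1659, end=1759),
    DomainRegion(name="BAF250_C", start=1939, end=2282),
]

#: Pfam boundaries for the two annotated domains.
PFAM_REGIONS = [
    DomainRegion(name="ARID", start=1000, end=1119),
    DomainRegion(name="BAF250_C", start=1974, end=2231),
]

REGION_PRESETS = {"seg-hca": SEGHCA_REGIONS, "pfam": PFAM_REGIONS}

#: DNA-binding residues of the BAF250a ARID (NMR chemical-shift perturbation).
DNA_BINDING_ARID = ResidueSet(
    name="ARID DNA-binding",
    residues={1002: "T", 1003: "T", 1004: "T", 1005: "N", 1006: "E",
              1041: "L", 1044: "V", 1046: "R", 1047: "K", 1072: "K",
              1073: "W", 1074: "R", 1091: "S", 1092: "L", 1093: "K",
              1094: "K", 1096: "Y", 1097: "I"},
)

#: ARID residues selectively conserved when ARID co-occurs with BAF250_C
#: (the ARID+BAF250_C architecture).  Union of the exposed-conserved set
#: mapped on the ARID structure and the two additional conserved positions
#: reported mutated in tumours (M1022, K1106).
ARCH2_CONSERVED_ARID = ResidueSet(
    name="ARCH2-specific conserved (ARID)",
    residues={1019: "E", 1021: "K", 1022: "M", 1026: "R", 1028: "L",
              1033: "E", 1034: "K", 1036: "M", 1041: "L", 1044: "V",
              1046: "R", 1056: "V", 1059: "K", 1072: "K", 1074: "R",
              1078: "T", 1081: "N", 1084: "T", 1085: "S", 1087: "S",
              1091: "S", 1094: "K", 1095: "Q", 1097: "I", 1102: "A",
              1106: "K"},
)

#: ARCH2-conserved positions that are not DNA-binding: the published
#: mutation accounting is disjoint — mutated DNA-binding residues are
#: reported separately from mutated conserved-only residues.
ARCH2_CONSERVED_NOT_DNA_BINDING = ResidueSet(
    name="ARCH2-specific conserved, non-DNA-binding (ARID)",
    residues={p: aa for p, aa in ARCH2_CONSERVED_ARID.residues.items()
              if p not in DNA_BINDING_ARID.residues},
)

#: Hydrophobic-core residues of the ARID (fold maintenance).
ARID_CORE = ResidueSet(
    name="ARID hydrophobic core",
    residues={1058: "V", 1061: "I", 1067: "V", 1076: "L", 1093: "K", 1096: "Y"},
)

#: Reconstructed COSMIC missense positions on the two domains.  Positions on
#: the ARID: three DNA-binding residues (T1004, R1046, R1074) and three
#: ARCH2-conserved residues (M1022, R1026, K1106); on BAF250_C: the seven
#: reported residues.  Alt alleles are synthetic placeholders.
COSMIC_DOMAIN_MISSENSE = [
    MutationRecord(position=1004, ref_aa="T", alt_aa="A"),
    MutationRecord(position=1022, ref_aa="M", alt_aa="I"),
    MutationRecord(position=1026, ref_aa="R", alt_aa="Q"),
    MutationRecord(position=1046, ref_aa="R", alt_aa="W"),
    MutationRecord(position=1074, ref_aa="R", alt_aa="C"),
    MutationRecord(position=1106, ref_aa="K", alt_aa="N"),
    MutationRecord(position=1982, ref_aa="V", alt_aa="M"),
    MutationRecord(position=1989, ref_aa="R", alt_aa="C"),
    MutationRecord(position=2050, ref_aa="W", alt_aa="R"),
    MutationRecord(position=2087, ref_aa="G", alt_aa="R"),
    MutationRecord(position=2088, ref_aa="L", alt_aa="P"),
    MutationRecord(position=2089, ref_aa="L", alt_aa="V"),
    MutationRecord(position=2106, ref_aa="L", alt_aa="F"),
]
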