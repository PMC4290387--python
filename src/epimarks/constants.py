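"""Shared vocabulary: mark names, species naming, default thresholds."""

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "PolII")
#: marks called as narrow peaks with a per-peak FDR
NARROW_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "PolII")
#: marks called as broad domains with a domain score
BROAD_MARKS = ("H3K27me3",)

#: index of the repressive mark (anti-correlated with the active four)
REPRESSIVE_INDEX = MARKS.index("H3K27me3")

#: default species naming for up to three species cohorts
SPECIES_NAMES = ("human", "chimpanzee", "rhesus")
SPECIES_PREFIXES = {"human": "H", "chimpanzee": "C", "rhesus": "R"}

RNA_NODE = "RNA"
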