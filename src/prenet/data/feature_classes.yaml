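# Default mapping from regulatory feature_type labels to the three broad
# regulatory classes used in PRE scoring:
#   PEX - promoter/enhancer/transcription-activating evidence (positive weight)
#   R   - repressive evidence (negative weight)
#   ZQI - inert/quiescent/uninformative (zero weight, still counted in totals)
# Edit or replace this file to match the vocabulary of your catalogue export.
promoter: PEX
enhancer: PEX
transcription: PEX
TFBS: PEX
protein_binding: PEX
DHS: PEX
H3K4me1: PEX
H3K4me3: PEX
H3K27ac: PEX
H3K36me3: PEX
H3K9ac: PEX
eQTL: PEX
repressor: R
repressed: R
H3K27me3: R
H3K9me3: R
heterochromatin: R
polycomb: R
quiescent: ZQI
inert: ZQI
insulator: ZQI
CTCF: ZQI
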