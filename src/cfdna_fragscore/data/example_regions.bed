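# SYNTHETIC placeholder coordinates for the OCR1/OCR2/CCR target loci.
# The designed assay coordinates are not published; these intervals only
# exercise the interval machinery (OCR1/OCR2 on chr8, CCR pericentromeric
# on chr12) and carry no biological meaning.
chr8	127735000	127736000	OCR1
chr8	128076000	128077000	OCR2
chr12	34830000	34831000	CCR
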