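# CHIP driver genes: somatic variants annotated to these genes are never
# counted as clock-like passengers. Edit to extend the list.
DNMT3A
ASXL1
TET2
JAK2
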