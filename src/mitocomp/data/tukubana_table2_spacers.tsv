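# Printed intergenic/overlap lengths (bp) between each listed gene and the next
# gene clockwise, as annotated in the source record. Blank rows of the original
# column are omitted (they correspond to abutting genes, gap 0).
# The final row (nad2 -> cox1, across the origin) prints 25 while the recorded
# coordinates imply a 26 bp circular gap; it is kept here verbatim and flagged.
token	printed_gap	verified
cox2	1	yes
atp8	-2	yes
trnY	-2	yes
trnG	-3	yes
trnQ	1	yes
nad6	-8	yes
cob	16	yes
trnW	1	yes
atp6	-2	yes
trnE	1	yes
nad4l	-7	yes
nad4	-2	yes
trnA	-1	yes
nad1	5	yes
nad3	-3	yes
trnS1	1	yes
nad2	25	no
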