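keyword	category
tail sheath	tail_sheath
sheath protein	tail_sheath
tape measure	tape_measure
large terminase	terminase_large
terminase large	terminase_large
terminase, large	terminase_large
small terminase	terminase_small
terminase small	terminase_small
terminase, small	terminase_small
terminase	terminase_large
portal	portal
major capsid	head
capsid	head
head protein	head
head-tail	neck
head closure	neck
neck	neck
head	head
baseplate	baseplate
base plate	baseplate
tail fiber	tail
tail fibre	tail
tail spike	tail
tailspike	tail
tail assembly	tail
tail protein	tail
tail	tail
integrase	integrase
recombinase	integrase
excisionase	integrase
transposase	transposase
endolysin	lysis
lysozyme	lysis
lysin	lysis
spanin	lysis
holin	lysis
lysis	lysis
polymerase	nucleic_acid_metabolism
helicase	nucleic_acid_metabolism
ligase	nucleic_acid_metabolism
primase	nucleic_acid_metabolism
exonuclease	nucleic_acid_metabolism
endonuclease	nucleic_acid_metabolism
nuclease	nucleic_acid_metabolism
methyltransferase	nucleic_acid_metabolism
ribonucleotide reductase	nucleic_acid_metabolism
single-stranded dna-binding	nucleic_acid_metabolism
replication	nucleic_acid_metabolism
topoisomerase	nucleic_acid_metabolism
repressor	regulation
antirepressor	regulation
regulator	regulation
regulatory	regulation
transcription factor	regulation
sigma factor	regulation
anti-sigma	regulation
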