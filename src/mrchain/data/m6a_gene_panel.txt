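# m6A regulator gene panel: the 24 writers/erasers/readers with significant
# blood cis-eQTL instruments; used as the default exposure panel in example
# configurations.
ALKBH1
ALKBH3
ALKBH5
CBLL1
CEBPZ
ELAVL1
FTO
IGF2BP2
IGF2BP3
KIAA1429
METTL14
METTL16
METTL3
METTL5
METTL7A
RBM15
RBM15B
SMAD2
SMAD3
WTAP
YTHDC2
YTHDF2
YTHDF3
ZC3H13
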