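# Small canonical human housekeeping panel (override with your own list).
ACTB
GAPDH
B2M
HPRT1
RPLP0
TBP
PGK1
PPIA
GUSB
TFRC
UBC
YWHAZ
SDHA
LDHA
PGAM1
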