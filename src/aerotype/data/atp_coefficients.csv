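reaction_id,coefficient
PPK,-1
PPK2,-1
ATPS4rpp,1
PFK_2,-1
HEX1,-1
PYK,1
PFK,-1
PPS,-1
PGK,-1
GLGC,-1
PFK_3,-1
GART,-1
PPAKr,1
ACCOAL,-1
ACS,-1
ACKr,-1
SUCOAS,-1
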