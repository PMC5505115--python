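# Accessions removed from reports by default: the proteases used during
# sample preparation plus common laboratory contaminants (keratins, BSA).
TRYP_PIG
TRY1_BOVIN
TRY2_BOVIN
CTRA_BOVIN
CTRB_BOVIN
PEPA_PIG
ALBU_BOVIN
K1C9_HUMAN
K1C10_HUMAN
K1C14_HUMAN
K2C1_HUMAN
K22E_HUMAN
K2C5_HUMAN
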