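>hsa-miR-200a-3p miRBase v19 mature sequence
UAACACUGUCUGGUAACGAUGU
>hsa-miR-200b-3p miRBase v19 mature sequence
UAAUACUGCCUGGUAAUGAUGA
>hsa-miR-200c-3p miRBase v19 mature sequence
UAAUACUGCCGGGUAAUGAUGGA
>hsa-miR-141-3p miRBase v19 mature sequence
UAACACUGUCUGGUAAAGAUGG
>hsa-miR-429 miRBase v19 mature sequence
UAAUACUGUCUGGUAAAACCGU
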