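>miR-302a miRBase mature hsa-miR-302a-3p; guide strand
UAAGUGCUUCCAUGUUUUGGUGA
>miR-372 miRBase mature hsa-miR-372-3p; guide strand, star strand not annotated
AAAGUGCUGCGACAUUUGAGCGU
>miR-373 miRBase mature hsa-miR-373-3p; guide strand
GAAGUGCUUCGAUUUUGGGGUGU
>miR-520c miRBase mature hsa-miR-520c-3p; guide strand
AAAGUGCUUCCUUUUAGAGGGU
>miR-520f miRBase mature hsa-miR-520f-3p; guide strand, seed window 1-7
AAGUGCUUCCUUUUAGAGGGUU
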