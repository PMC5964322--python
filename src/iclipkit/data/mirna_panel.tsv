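# Conserved-miRNA panel for 3'UTR 7mer-A1 seed-match profiling.
# Ubiquitous (let-7a, miR-125b), stem cell (miR-302a), muscle (miR-1),
# blood (miR-150) and brain-enriched (miR-9, miR-124, miR-128, miR-132,
# miR-138) representatives.
# Provenance: mature sequences per miRBase release 22 (mmu/hsa identical
# for these guide strands).
name	mature_seq
let-7a-5p	UGAGGUAGUAGGUUGUAUAGUU
miR-125b-5p	UCCCUGAGACCCUAACUUGUGA
miR-302a-3p	UAAGUGCUUCCAUGUUUUGGUGA
miR-1-3p	UGGAAUGUAAAGAAGUAUGUAU
miR-150-5p	UCUCCCAACCCUUGUACCAGUG
miR-9-5p	UCUUUGGUUAUCUAGCUGUAUGA
miR-124-3p	UAAGGCACGCGGUGAAUGCC
miR-128-3p	UCACAGUGAACCGGUCUCUUU
miR-132-3p	UAACAGUCUACAGCCAUGGUCG
miR-138-5p	AGCUGGUGUUGUGAAUCAGGCCG
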