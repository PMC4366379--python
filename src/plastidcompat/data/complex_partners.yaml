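# Curated nuclear counterparts for plastid candidate loci: for each plastid
# candidate, the multi-subunit complex its product belongs to and the
# nuclear-encoded partner subunits, with keywords for gene-table searches.
accD:
  complex: heteromeric plastid acetyl-CoA carboxylase (ACCase)
  partners:
    - alpha subunit of carboxyltransferase (alpha-CT)
    - biotin carboxyl carrier protein (BCCP)
    - biotin carboxylase (BC)
  keywords:
    - biotin carboxyl carrier protein
    - biotin carboxylase
    - carboxyltransferase
    - acetyl-CoA carboxylase
rpoB:
  complex: plastid-encoded RNA polymerase (PEP)
  partners:
    - sigma factors
    - CSP41
    - iron superoxide dismutase 3
    - plastid transcription kinase PTK
  keywords:
    - sigma factor
    - CSP41
    - superoxide dismutase
    - transcription kinase
ycf1:
  complex: chloroplast inner-envelope protein import (TIC, 1-MD complex)
  partners:
    - Tic100
    - Tic56
    - Tic20-I
  keywords:
    - Tic100
    - Tic56
    - Tic20
ycf2:
  complex: unknown
  partners: []
  keywords: []
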