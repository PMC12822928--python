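>BLG_BOS synthetic Bos taurus beta-lactoglobulin stand-in (tryptic-peptide concatenation; TPEVDDEALEK locus from the literature)
VLVLDTDYKVYVEELKPTPEGDLEILLQKGLDIQKTPEVDDEALEKIPAVFKWENGECAQ
KLIVTQTMKENSAEPEQSLVCQCLVR
>BLG_OVIS synthetic Ovis aries beta-lactoglobulin stand-in (TPEVDNEALEK locus: N at position 6)
VLVLDTDYKVYVEELKPTPEGDLEILLQKGLDIQKTPEVDNEALEKALPMHIRIDALNEN
K
>BLG_CAPRA synthetic Capra hircus beta-lactoglobulin stand-in
VLVLDTDYKVYVEELKPTPEGDLEILLQKGLDIQKALPMHIRFNPTQLEGQCHVK
>BLG1_EQUUS synthetic Equus caballus beta-lactoglobulin-1 stand-in
LVSDLTEKANIPQTMRFTDSLAVRENSAEPEQSLVCQCLVR
>BLG2_EQUUS synthetic Equus caballus beta-lactoglobulin-2 stand-in
SLAMTASDISLLDAQSAPLRVEPTPLPLR
>CASA1_BOS synthetic Bos taurus alpha-S1-casein stand-in
YLGYLEQLLREDVPSERHQGLPQEVLNENLLRFFVAPFPEVFGK
>CASA1_OVIS synthetic Ovis aries alpha-S1-casein stand-in
YLGYLEQLLREDVPSERAYFYPELFRVNELSTK
>CASA1_CAPRA synthetic Capra hircus alpha-S1-casein stand-in
YLGYLEQLLREDVPSERAYFYPELFRISMPELFR
>BTN1A1_BOS synthetic Bos taurus butyrophilin subfamily 1 member A1 stand-in
AVLHPLEVRTLEPQSALK
>WP_229715011 synthetic bacterial hypothetical-protein homolog carrying a casein peptide (genome-contamination artefact class)
YLGYLEQLLRSSGDATNK
>MBO8907834 synthetic bacterial lipocalin/fatty-acid binding homolog carrying a BLG peptide
TPEVDDEALEKAVDGLTNK
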