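accession	protein_name	lineage
BLG_BOS	BLG	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Bovinae>Bos
BLG_OVIS	BLG	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Caprinae>Ovis
BLG_CAPRA	BLG	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Caprinae>Capra
BLG1_EQUUS	BLG-1	Root>Mammalia>Perissodactyla>Equidae>Equus
BLG2_EQUUS	BLG-2	Root>Mammalia>Perissodactyla>Equidae>Equus
CASA1_BOS	Alpha-S1-casein	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Bovinae>Bos
CASA1_OVIS	Alpha-S1-casein	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Caprinae>Ovis
CASA1_CAPRA	Alpha-S1-casein	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Caprinae>Capra
BTN1A1_BOS	BTN1A1	Root>Mammalia>Artiodactyla>Pecora>Bovidae>Bovinae>Bos
WP_229715011	hypothetical protein	Root>Bacteria>Bacilli>Jeotgalicoccus
MBO8907834	lipocalin/fatty-acid binding family protein	Root>Bacteria>Bacilli>Staphylococcus
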