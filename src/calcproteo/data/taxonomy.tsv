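name	rank	parent
Root	root
Bacteria	superkingdom	Root
Bacilli	class	Bacteria
Jeotgalicoccus	genus	Bacilli
Staphylococcus	genus	Bacilli
Mammalia	class	Root
Artiodactyla	order	Mammalia
Pecora	infraorder	Artiodactyla
Bovidae	family	Pecora
Bovinae	subfamily	Bovidae
Bos	genus	Bovinae
Caprinae	subfamily	Bovidae
Ovis	genus	Caprinae
Capra	genus	Caprinae
Perissodactyla	order	Mammalia
Equidae	family	Perissodactyla
Equus	genus	Equidae
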