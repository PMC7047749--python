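subfamily	tribe	taxon	length_bp
Epidendroideae	Collabieae	Calanthe aristulifera	158204
Epidendroideae	Collabieae	Calanthe bicolor	158070
Epidendroideae	Cymbidieae	Dipodium roseum	141209
Epidendroideae	Epidendreae	Corallorhiza maculata var. maculata	146198
Epidendroideae	Epidendreae	Cremastra unguiculata	159341
Epidendroideae	Epidendreae	Oreorchis patens	158542
Epidendroideae	Gastrodieae	Gastrodia elata	35056
Epidendroideae	Malaxideae	Bulbophyllum inconspicuum	149548
Epidendroideae	Malaxideae	Dendrobium moniliforme	151711
Epidendroideae	Malaxideae	Dendrobium moniliforme 'Royal Dream'	151695
Epidendroideae	Malaxideae	Dendrobium moniliforme 'Sangeum'	151711
Epidendroideae	Malaxideae	Liparis auriculata	153460
Epidendroideae	Malaxideae	Liparis makinoana	153093
Epidendroideae	Neottieae	Epipactis thunbergii	159279
Epidendroideae	Vandeae	Sedirea japonica	146942
Orchidoideae	Cranichideae	Goodyera rosulacea	152831
Orchidoideae	Cranichideae	Hetaeria shikokiana	130934
Orchidoideae	Orchideae	Amitostigma gracile	156120
Orchidoideae	Orchideae	Dactylorhiza viridis var. coreana	153549
Orchidoideae	Orchideae	Galearis cyclochila	153928
Orchidoideae	Orchideae	Gymnadenia conopsea	153876
Orchidoideae	Orchideae	Habenaria chejuensis	153896
Orchidoideae	Orchideae	Habenaria flagellifera	151210
Orchidoideae	Orchideae	Platanthera mandarinorum	154162
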