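species	genus	accession	genome_size	gc_percent	lsc	ssc	ir
Dendrosenecio johnstonii	Dendrosenecio	MG560050	150607	37.5	83469	17754	24692
Dendrosenecio meruensis	Dendrosenecio	MG560049	150587	37.5	83448	17755	24692
Dendrosenecio elgonensis	Dendrosenecio	KY434194	150548	37.5	83403	17771	24687
Dendrosenecio keniodendron	Dendrosenecio	KY434193	150555	37.5	83418	17755	24691
Dendrosenecio battiscombei	Dendrosenecio	KY434195	150556	37.5	83410	17762	24692
Dendrosenecio brassiciformis	Dendrosenecio	MG560051	150551	37.5	83424	17747	24690
Senecio moorei	Senecio	MH483949	151204	37.2	83278	18300	24813
Senecio keniophytum	Senecio	MH483946	151413	37.2	83422	18277	24857
Senecio purtschelleri	Senecio	MH483947	151191	37.2	83243	18302	24823
Senecio schweinfurthii	Senecio	MH483950	151260	37.2	83255	18389	24823
Senecio roseiflorus	Senecio	MH483948	151228	37.2	83329	18279	24810
Jacobaea vulgaris	Jacobaea	NC_015543	150689	37.3	82855	18277	24777
Ligularia fischeri	Ligularia	KT988070	151133	37.5	83238	18233	24831
Pericallis hybrida	Pericallis	NC_031898	151267	37.3	85751	18331	23591
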