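tribe	species	pair_end_reads	percent_on_target	loci_obtained	percent_recovery_length	loci_retained
Bignonieae	Adenocalymma acutissimum1	18401073	76.1	757	93.3	676
Bignonieae	Amphilophium paniculatum	28119426	76.9	758	94.3	676
Bignonieae	Anemopaegma arvense	8486773	69.7	757	92.8	675
Bignonieae	Bignonia capreolata	4863524	80.1	759	94.5	676
Bignonieae	Callichlamys latifolia	11089886	75.2	757	94.7	676
Crescentieae	Crescentia cujete	6770767	80.4	759	96	676
Bignonieae	Cuspidaria convoluta	7953194	65.3	758	93.7	676
Tecomeae	Cybistax antisyphilitica	14574220	68.4	758	95.2	675
Bignonieae	Dolichandra chodatii	3077426	68.7	757	93.8	676
Bignonieae	Dolichandra cynanchoides	11401675	71.3	758	95	676
Bignonieae	Dolichandra dentata	9614141	79.4	758	94	676
Bignonieae	Dolichandra hispida	8467292	79.2	759	94	677
Bignonieae	Dolichandra quadrivalvis	10465488	80.7	758	93.8	676
Bignonieae	Dolichandra uncata	21119851	78.1	756	93	675
Bignonieae	Dolichandra unguis-cati1	15336452	80	755	92.1	674
Bignonieae	Dolichandra unguis-cati2	14553233	74.8	756	92.5	674
Bignonieae	Dolichandra unguis-cati3	15517980	49.1	757	92.5	675
Bignonieae	Fridericia speciosa	4029504	76.8	755	93.5	674
Tecomeae	Godmania aesculifolia	6104436	4.4	732	85.9	653
Tecomeae	Handroanthus catarinensis	13546481	66.6	758	94.9	675
Jacarandeae	Jacaranda mimosifolia	5051624	68.6	741	82.7	661
Bignonieae	Lundia longa	5298119	80.3	755	92.9	673
Bignonieae	Manaosella cordifolia	27279881	77.8	756	94.3	674
Bignonieae	Mansoa hirsuta	3940708	74.9	759	92.7	676
Bignonieae	Martinella obovata	5605255	75.6	758	94.6	676
Oroxyleae	Nyctocalos cuspidatum	55042136	79.6	754	94.1	673
Bignonieae	Pachyptera incarnata	7932766	75.6	756	94.1	674
Crescentieae	Parmentiera cereifera	71238833	80.8	754	93.1	673
Bignonieae	Perianthomega vellozoi	5814004	81.5	755	95	675
Bignonieae	Pleonotoma jasminifolia	7456086	78.3	756	94.2	675
Tecomeae	Podranea ricasoliana	16729542	78.7	755	91.9	675
Bignonieae	Pyrostegia venusta	5081154	66.8	757	91.7	675
Bignonieae	Stizophyllum perforatum	12840685	79.8	758	94.6	676
Tecomeae	Tabebuia roseoalba	9587299	82.1	756	95.6	675
Bignonieae	Tanaecium jaroba	23112074	76.1	758	94	676
Tecomeae	Tecoma stans	21512775	61.4	755	91.7	674
Bignonieae	Tynanthus polyanthus	11207016	80.2	757	93.7	675
Bignonieae	Xylophragma pratense	6210566	75	754	93.4	673
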