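description	size	overlap	expect	ratio	pValue	FDR	database
neuron to neuron synapse	322	49	18.31	2.68	2.18E-10	2.09E-07	CC
postsynaptic specialization	327	47	18.59	2.53	3.49E-09	1.67E-06	CC
glutamatergic synapse	368	50	20.93	2.39	7.51E-09	2.39E-06	CC
glutamate receptor signaling pathway	78	19	4.44	4.28	4.87E-08	1.16E-05	BP
regulation of neuron projection development	422	52	24.00	2.17	1.01E-07	1.93E-05	BP
cell part morphogenesis	428	52	24.34	2.14	1.59E-07	2.54E-05	BP
positive regulation of cell projection organization	321	42	18.25	2.30	3.50E-07	4.79E-05	BP
synaptic membrane	396	47	22.52	2.09	1.25E-06	1.44E-04	CC
neuron spine	182	28	10.35	2.71	1.36E-06	1.44E-04	CC
positive regulation of cell component biogenesis	349	42	19.85	2.12	3.24E-06	3.10E-04	BP
Axon guidance	216	31	11.17	2.77	2.20E-07	2.68E-04	React
Membrane Trafficking	457	50	23.64	2.12	3.73E-07	2.68E-04	React
Glutamatergic synapse	116	21	6.00	3.50	4.34E-07	2.68E-04	KEGG
Vesicle-mediated transport	483	51	24.99	2.04	8.44E-07	3.20E-04	React
Calcium Regulation in the Cardiac Cell	132	22	6.83	3.22	1.01E-06	3.20E-04	Wiki
Signaling by Receptor Tyrosine Kinases	304	37	15.73	2.35	1.04E-06	3.20E-04	React
Circadian entrainment	99	18	5.12	3.51	2.70E-06	7.15E-04	KEGG
MAPK family signaling cascades	218	28	11.28	2.48	7.76E-06	1.79E-03	React
Neuronal System	258	31	13.35	2.32	1.02E-05	2.09E-03	React
Signaling by VEGF	80	15	4.14	3.62	1.24E-05	2.27E-03	React
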