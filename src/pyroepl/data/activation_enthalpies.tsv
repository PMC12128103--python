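reactant	product	leaving	dft_0	cbs_0	g4_0	dlpno_0	dlpnocbs_0	dft_298	cbs_298	g4_298	dlpno_298	dlpnocbs_298
xylose	D-xylose	none	49.68	38.19	45.55	49.36	48.86	45.54	37.30	45.54	45.35	44.85
xylose	FF1	H2O	76.21	71.20a	71.41	74.96	74.52	72.84	71.30a	71.47	71.70	71.26
xylose	FF2	H2O	70.25	56.68	65.07	68.71	68.31	70.25	56.68	65.09	65.86	65.47
xylose	AXP1	H2O	77.19	64.27	69.11	74.72	75.07	71.81	63.48	69.65	69.90	70.25
xylose	AXP2	H2O	81.68	67.01	80.73	87.47	86.99	76.07	66.46	81.08	82.43	81.95
xylose	AXP3	H2O	80.08	66.41	73.49	79.48	78.69	74.78	65.96	73.76	74.47	73.68
xylose	AXP4	H2O	81.45	67.78	74.86	81.22	80.44	76.08	67.40	75.20	76.04	75.26
xylose	AXP5	H2O	79.73	66.27	74.05	80.37	79.60	74.55	65.69	74.39	75.25	74.48
xylose	AXP6	H2O	87.20	73.70	74.38	80.87	80.63	82.00	73.27	74.85	75.44	75.20
xylose	AXP7	H2O	75.55	62.03	71.49	77.20	76.16	70.57	61.64	71.56	71.98	70.94
2-O-acetyl-xylose	OADXP	none	45.56	43.99	43.91	45.23	44.70	42.65	43.89	43.79	41.42	40.88
2-O-acetyl-xylose	FFL1	CH3COOH	-	-	-	-	-	-	-	-	-	-
2-O-acetyl-xylose	FFL2	CH3COOH	71.64a	65.49	65.27	69.02a	68.71a	68.44a	65.61	65.35	64.51a	64.04a
2-O-acetyl-xylose	AXPL1	H2O	75.25	68.04	67.72	71.45	71.07	69.60	70.49	67.94	66.95	66.58
2-O-acetyl-xylose	AXPL2	CH3COOH	76.33	73.76	73.28	77.68	78.15	71.17	73.58	73.80	72.87	73.35
2-O-acetyl-xylose	AXPL3	CH3COOH	77.76	65.25	65.14	69.32	69.04	72.57	71.63	65.43	64.31	64.03
2-O-acetyl-xylose	AXPL4	H2O	75.77	72.43	71.94	76.50	75.72	70.84	72.72	72.19	71.72	70.94
2-O-acetyl-xylose	AXPL5	H2O	70.94	71.49	71.32	75.43	74.47	65.77	65.55	71.43	70.72	69.77
2-O-acetyl-xylose	AXPL6	H2O	79.37	73.10	72.38	77.67	76.93	74.39	74.32	72.79	72.46	71.72
2-O-acetyl-xylose	AXPL7	H2O	75.25	70.38	69.78	74.72	74.02	66.07	68.33	69.87	69.24	68.53
4-O-methyl-D-glucuronicacid	DGLA	none	51.87	47.77	47.66	51.57	51.13	47.36	47.76	47.47	47.19	46.75
4-O-methyl-D-glucuronicacid	FFL1	H2O	82.85	76.77a	76.70a	81.22	80.78	79.21	77.02a	76.99a	77.70	77.26
4-O-methyl-D-glucuronicacid	FFL2	H2O	67.35	60.91	61.01	64.29	64.71	64.66	60.94	61.03	61.69	62.11
4-O-methyl-D-glucuronicacid	AXPL1	H2O	75.64	70.19	68.79	76.13	76.40	62.58	64.08	69.27	71.14	71.41
4-O-methyl-D-glucuronicacid	AXPL2	H2O	85.70	75.67	75.29	86.12	85.60	74.73	72.85	75.10	81.92	81.40
4-O-methyl-D-glucuronicacid	AXPL3	H2O	80.77	74.82	74.29	80.49	79.61	73.68	74.23	74.60	75.50	74.61
4-O-methyl-D-glucuronicacid	AXPL4	H2O	73.24	69.40	68.89	74.43	73.22	68.71	69.38	68.78	70.03	68.82
4-O-methyl-D-glucuronicacid	AXPL5	H2O	78.65	73.87	73.51	79.42	78.84	75.62	75.19	73.84	74.60	74.02
4-O-methyl-D-glucuronicacid	AXPL6	CH3OH	79.67	72.23	72.28	79.89	79.19	81.37	75.53	72.92	75.10	74.41
4-O-methyl-D-glucuronicacid	AXPL7	CH3OH	66.35	63.95	63.53	67.66	67.08	70.49	70.62	63.70	64.00	63.42
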