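# Published reference table: empirical sensitivity, specificity and Youden's
# index (percentage points) of the A2 statistic at integer cutoffs ">= c",
# for discriminating paired-carcinoma pairs from unrelated-individual (UI),
# full-sibling (FS) and parent-offspring (PO) pairs over a 27-locus
# autosomal STR panel, as printed in the source study's cutoff table.
# Used for worked examples and internal-consistency checks.
cutoff	ui_sensitivity	ui_specificity	ui_youden	fs_sensitivity	fs_specificity	fs_youden	po_sensitivity	po_specificity	po_youden
1	100	0.04848	0.04848	100	3.636	3.636	100	0.9091	0.9091
2	100	0.04848	0.04848	100	3.636	3.636	100	0.9091	0.9091
3	100	0.1697	0.1697	100	3.636	3.636	100	0.9091	0.9091
4	100	0.7515	0.7515	100	3.636	3.636	100	4.545	4.545
5	100	2.642	2.642	100	3.636	3.636	100	11.82	11.82
6	100	7.03	7.03	100	3.636	3.636	100	22.73	22.73
7	100	14.47	14.47	100	3.636	3.636	100	38.18	38.18
8	100	24.46	24.46	100	7.273	7.273	100	53.64	53.64
9	100	39.25	39.25	100	18.18	18.18	100	67.27	67.27
10	100	54.59	54.59	100	29.09	29.09	100	79.09	79.09
11	100	68.78	68.78	100	40	40	100	85.45	85.45
12	100	80.65	80.65	100	60	60	100	92.73	92.73
13	100	89.55	89.55	100	74.55	74.55	100	97.27	97.27
14	100	95.56	95.56	100	85.45	85.45	100	99.09	99.09
15	100	98.3	98.3	100	89.09	89.09	100	100	100
16	100	99.39	99.39	100	90.91	90.91	100	100	100
17	98.18	99.85	98.03	98.18	96.36	94.54	98.18	100	98.18
18	98.18	99.95	98.13	98.18	98.18	96.36	98.18	100	98.18
19	98.18	100	98.18	98.18	100	98.18	98.18	100	98.18
20	98.18	100	98.18	98.18	100	98.18	98.18	100	98.18
21	98.18	100	98.18	98.18	100	98.18	98.18	100	98.18
22	96.36	100	96.36	98.18	100	98.18	96.36	100	96.36
23	96.36	100	96.36	96.36	100	96.36	85.45	100	85.45
24	96.36	100	96.36	96.36	100	96.36	85.45	100	85.45
25	96.36	100	96.36	96.36	100	96.36	85.45	100	85.45
26	85.45	100	85.45	85.45	100	85.45	85.45	100	85.45
27	67.27	100	67.27	67.27	100	67.27	67.27	100	67.27
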