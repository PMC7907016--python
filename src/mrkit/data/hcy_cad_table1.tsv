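snp	gene	chr	effect_allele	other_allele	eaf	f_printed	beta_exp	se_exp	pval_exp	beta_out	se_out	pval_out
rs12134663	MTHFR	1	C	A	0.21	45	0.101	0.011	2.54e-21	-0.0176777	0.0364898	0.62806302
rs12780845	CUBN	10	A	G	0.65	56	0.0529	0.009	7.8e-10	0.00729057	0.0289842	0.80140001
rs1801222	CUBN	10	A	G	0.34	41	0.0453	0.007	8.43e-10	-0.0258042	0.0273547	0.34551701
rs2275565	MTR	1	G	T	0.79	43	0.0542	0.009	1.96e-10	0.00873448	0.0325477	0.788423
rs234709	CBS	21	C	T	0.55	113	0.0718	0.007	3.9e-24	0.0464321	0.0267226	0.0822889
rs42648	GTPB10	7	G	A	0.63	30	0.0395	0.007	1.97e-08	0.0168946	0.0272545	0.535335
rs4660306	MMACHC	1	T	C	0.33	37	0.0435	0.007	2.33e-09	-0.0366147	0.0283157	0.19598
rs7130284	NOX4	11	C	T	0.93	89	0.1242	0.013	1.88e-20	0.0616853	0.0509219	0.22575299
rs838133	FUT2	19	A	G	0.45	39	0.0422	0.007	7.48e-09	0.00416956	0.0276868	0.88029301
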