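rho_T	mu_T	rho_A	alpha_T_experimental	alpha_T_fitted
2.786e-8	0.03333333333333333	0.016666666666666666	1.393e-7	1.401e-7
2.880e-8	0.03333333333333333	0.025	1.440e-7	1.441e-7
3.170e-8	0.03333333333333333	0.05	1.585e-7	1.577e-7
3.022e-8	0.07142857142857142	0.016666666666666666	1.511e-7	1.507e-7
3.120e-8	0.07142857142857142	0.025	1.560e-7	1.554e-7
3.392e-8	0.07142857142857142	0.05	1.696e-7	1.705e-7
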