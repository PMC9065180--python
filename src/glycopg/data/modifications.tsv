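# Sequence-modification catalogue, v1.
# delta is recomputed at load time from formula_gain/formula_loss; the
# printed_delta column records the nominal value at its customary precision
# (decimal comma accepted) and is used only for provenance checks.
name	targets	formula_gain	formula_loss	printed_delta
carbamidomethyl	C	C2H3NO	-	57.0215
oxidation	M	O	-	15.9949
deamidation	N,Q	O	NH	0.9840
N-term_formylation	protein-N-term	CO	-	27.994
N-term_acetylation	protein-N-term	C2H2O	-	42.0106
pyro-Glu	Q@N-term	-	NH3	-17.0265
Cys_N-term_ammonia-loss	C@N-term	-	NH3	-17.0265
Lys->aminoadipic_semialdehyde	K	O	NH3	-1.0316
Arg->glutamic_semialdehyde	R	O	CH5N3	-43.0534
Pro->pyroglutamic_acid	P	O	H2	13,9794
Trp->hydroxykynurenine	W	O2	C	19.9898
Trp->kynurenine	W	O	C	3,9949
Trp->N-formylkynurenine	W	O2	-	31.9898
Thr->2-amino-3-ketobutyric_acid	T	-	H2	-2.0156
Lys_methylation	K	CH2	-	14.0156
hydroxylation	F,P,H,W	O	-	15.9949
carbonylation	F,P,H,W	O	H2	13,9794
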