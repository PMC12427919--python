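rbp	categories
G3BP1	stress_granule
TIA1	stress_granule
TIAL1	stress_granule
EIF4G2	stress_granule
ELAVL1	stress_granule
FXR1	stress_granule
FXR2	stress_granule
CAPRIN1	stress_granule
DDX6	p_body
PUM1	p_body
PUM2	p_body
UPF1	p_body
DCP1A	p_body
DCP2	p_body
LSM14A	p_body
EDC3	p_body
IGF2BP1	m6a_reader
IGF2BP2	m6a_reader
IGF2BP3	m6a_reader
RBM15	m6a_reader,splicing
YTHDF1	m6a_reader
YTHDF2	m6a_reader,p_body
YTHDC1	m6a_reader,splicing
HNRNPK	splicing
HNRNPC	splicing
SRSF1	splicing
U2AF1	splicing
U2AF2	splicing
RBM42	splicing
SF3B4	splicing
PTBP1	splicing
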