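# kind: AMIDE_ANALOG
# net_charge: 0
# provenance: force-field
N	-0.5000
H	0.3000
C	0.5000
O	-0.5000
CT1	-0.1800
CT2	0.0200
H11	0.0600
H12	0.0600
H13	0.0600
H21	0.0600
H22	0.0600
H23	0.0600
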