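# kind: GLU_ANALOG
# net_charge: -1
# provenance: force-field
CD	0.7000
OE1	-0.8000
OE2	-0.8000
CG	-0.2200
HG2	0.0600
HG3	0.0600
CB	-0.1800
HB1	0.0600
HB2	0.0600
HB3	0.0600
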