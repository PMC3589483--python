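# kind: ARG_ANALOG
# net_charge: 1
# provenance: force-field
CZ	0.6400
NE	-0.7000
HE	0.4400
NH1	-0.8000
HH11	0.4600
HH12	0.4600
NH2	-0.8000
HH21	0.4600
HH22	0.4600
CD	0.2000
HD1	0.0600
HD2	0.0600
HD3	0.0600
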