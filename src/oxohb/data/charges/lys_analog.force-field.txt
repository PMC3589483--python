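# kind: LYS_ANALOG
# net_charge: 1
# provenance: force-field
NZ	-0.3000
HZ1	0.3300
HZ2	0.3300
HZ3	0.3300
CE	0.1300
HE1	0.0600
HE2	0.0600
HE3	0.0600
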