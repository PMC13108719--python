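# synthetic toy reference data (generated by splitpea.fixtures; not real biology)
pfam_a	pfam_b
PF00001.2	PF00003
PF00001	PF00004
PF00001	PF00007
PF00002.2	PF00003
PF00002	PF00005
PF00002	PF00007
PF00003.2	PF00005
PF00003	PF00007
PF00003	PF00008
PF00004.2	PF00008
PF00005	PF00006
PF00005	PF00008
PF00006.2	PF00007
PF00006	PF00008
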