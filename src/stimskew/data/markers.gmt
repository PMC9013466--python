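microglia	expected_present:microglia signature genes	Cx3cr1	Csf1r	Hexb	Olfml3	Tmem119
astrocyte	expected_absent:astrocyte markers	Gfap	Aldh1l1	Aqp4	Slc1a3
oligodendrocyte	expected_absent:oligodendrocyte markers	Mbp	Mog	Plp1	Sox10
neuron	expected_absent:neuron markers	Rbfox3	Snap25	Syt1	Tubb3
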