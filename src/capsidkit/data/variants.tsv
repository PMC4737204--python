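# Experimentally characterised lumazine-synthase capsid variants:
# interface point mutations and the oligomeric state observed in solution.
# 'mutations' uses author residue numbering of the AaLS pentamer
# (ionic network R21/R40, H-bond site H41, hydrophobic cluster L121/I125).
# 'toy_mutations' maps each site by role onto the synthetic dodecahedral
# capsid's 5-residue monomer (E1 salt anion, H2 hbond, L3 hydrophobic,
# A4 inward filler, R5 salt cation); L121 and I125 share the single toy
# hydrophobic site, so W6 collapses onto W5's toy specs.
#variant	mutations	toy_mutations	experimental_state
WT	-	-	capsid
W2	R40E,H41E	R5E,H2E	capsid
W3	R21E,R40E,H41E	E1R,R5E,H2E	capsid
W4	H41R,L121R	H2R,L3R	pentamer
W5	R40E,H41E,L121E	R5E,H2E,L3E	pentamer
W6	R40E,H41E,I125E	R5E,H2E,L3E	pentamer
W7	R40S,H41S,I125S	R5S,H2S,L3S	pentamer
W8	R40S,H41L,L121E	R5S,H2L,L3E	pentamer
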