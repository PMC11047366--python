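# Conserved sequence motifs of human COQ2 (UbiA-family signatures).
name	start	end
Asp134xxxAsp138	134	138
Tyr195xxxLys199	195	199
Asp255xxxAsp259	255	259
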