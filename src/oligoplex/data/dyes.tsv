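dye	excitation_nm	emission_nm	quencher
6-FAM	495	520	BHQ2
HEX	535	554	ZEN-IABkFQ
6-ROXN	575	602	BHQ2
Cy5	647	667	BHQ2
Quasar705	690	705	BHQ3
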