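# 15N analogue of nitroxide_14n.yaml: hyperfine tensor scaled by
# |gamma(15N)/gamma(14N)| = 1.4027; doublet spectra (I = 1/2).
nuclear_spin: 0.5
g_principal: [2.0085, 2.0061, 2.0022]
A_principal: [25.95, 25.95, 140.98]
A_unit: MHz
mw_frequency_ghz: 9.45
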