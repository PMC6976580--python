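# Typical literature g- and hyperfine-tensor values for a proxyl
# nitroxide in aqueous solution (NOT sample-calibrated values --
# substitute your own tensors for quantitative work).
nuclear_spin: 1
g_principal: [2.0085, 2.0061, 2.0022]
A_principal: [18.5, 18.5, 100.5]
A_unit: MHz
mw_frequency_ghz: 9.45
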