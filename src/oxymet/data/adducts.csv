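# Positive-mode ESI adducts. mass_shift is added to the neutral molecule
# before dividing by charge; shifts include the electron-mass correction
# (proton mass for +H, atom mass minus one electron otherwise).
label,mass_shift,charge
[M+H]+,1.00727646688,1
[M+Na]+,22.98922070,1
[M+NH4]+,18.03382555,1
[M+K]+,38.96315810,1
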