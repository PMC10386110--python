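# Monoisotopic atomic masses (Da), most abundant isotope per element.
# CODATA/IUPAC values; carbon-12 exact by definition.
symbol,monoisotopic_mass
H,1.00782503207
C,12.0
N,14.0030740052
O,15.9949146221
F,18.99840322
Na,22.98976928
Mg,23.9850417
Si,27.9769265325
P,30.97376163
S,31.97207100
Cl,34.96885268
K,38.96370668
Ca,39.96259098
Fe,55.9349375
Cu,62.9295975
Zn,63.9291422
Br,78.9183371
Se,79.9165213
I,126.904473
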