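# Synthetic open stand-in for a commercial natural-product library
# (e.g. the Dictionary of Natural Products). Not a redistribution of any
# database: records named after published actinobacterial metabolites carry
# either a literature molecular formula (mass computed at load time) or a
# published monoisotopic mass; all "Decoyin/Baikalomycin" entries are
# invented mass-decoys for specificity testing.
# activities is a semicolon-separated set; empty means unannotated.
name,formula,monoisotopic_mass,biological_source,activities
Desferrioxamine E,C27H48N6O9,,Streptomyces,antioxidant;siderophore;antibiotic
Ferrioxamine A2,,599.2496,Streptomyces,siderophore
Streptomyceamide B,,264.0747,Streptomyces,
Arginomycin,,436.2219,Streptomyces,antibiotic
Nivelactam,,439.2704,Streptomyces,
Antimycin A,,440.3655,Streptomyces,antibiotic;antifungal
"5,10,11-Trihydroxy-3-cadinanone",C15H26O4,,Streptomyces,
11-Methyl-2-tridecanone,C14H28O,,Streptomyces,
10-Methylhexadecanoic acid,C17H34O2,,Streptomyces,
Octahydro-7a-methyl-1-(1-methyl-2-oxopropyl)-5-oxo-1H-indene-4-propanoic acid,,294.181,Rhodococcus,antifungal
Decoyin A0,,357.2404,Streptomyces,
Decoyin A1,,182.0579,Streptomyces,
Decoyin A2,,226.1205,Streptomyces,antibiotic
Decoyin A3,,248.1418,Streptomyces,
Decoyin A4,,312.2302,Streptomyces,antioxidant
Decoyin A5,,365.1107,Streptomyces,
Decoyin A6,,412.3099,Streptomyces,
Decoyin A7,,455.2871,Streptomyces,antifungal
Decoyin A8,,498.1822,Streptomyces,
Decoyin A9,,533.3411,Streptomyces,siderophore
Decoyin A10,,602.4015,Streptomyces,
Decoyin A11,,655.3628,Streptomyces,antibiotic
Decoyin A12,,723.4457,Streptomyces,
Decoyin A13,,789.4122,Streptomyces,
Baikalomycin R1,,205.0866,Rhodococcus,
Baikalomycin R2,,338.2457,Rhodococcus,antibiotic
Baikalomycin R3,,471.2344,Rhodococcus,
Baikalomycin R4,,556.3166,Rhodococcus,antioxidant
Baikalomycin N1,,243.1012,Nocardia,
Baikalomycin N2,,389.2190,Nocardia,antifungal
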