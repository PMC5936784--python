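# Packaged pathway fixture: ids referenced by the builtin metabolite library.
pathway_id	name
PW001	Biosynthesis of 12-, 14- and 16-membered macrolides
PW002	Porphyrin and chlorophyll metabolism
PW003	Biosynthesis of type II polyketide products
PW004	Limonene and pinene degradation
PW005	Monoterpenoid biosynthesis
PW006	Glycolysis / Gluconeogenesis
PW007	Citrate cycle (TCA cycle)
PW008	Glycerophospholipid metabolism
PW009	Glycerolipid metabolism
PW010	Biosynthesis of amino acids
PW011	Purine metabolism
PW012	Carotenoid biosynthesis
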