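# Monoisotopic atomic masses (Da) of the most abundant isotope, IUPAC/AME values.
# element	mass	isotope
H	1.00782503	1H
C	12.00000000	12C
N	14.00307401	14N
O	15.99491462	16O
P	30.97376200	31P
S	31.97207117	32S
Na	22.98976928	23Na
K	38.96370649	39K
Cl	34.96885268	35Cl
F	18.99840316	19F
Mg	23.98504170	24Mg
Ca	39.96259086	40Ca
Fe	55.93493633	56Fe
Co	58.93319430	59Co
Si	27.97692653	28Si
Se	79.91652180	80Se
Br	78.91833760	79Br
I	126.90447300	127I
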