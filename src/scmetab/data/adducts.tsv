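# Positive-mode adducts (counter-ions). The m/z shift is the monoisotopic mass
# of the attached composition minus z electron masses (ions carry charge +1).
# name	composition	charge
+H+	H	1
+NH4+	NH4	1
+Na+	Na	1
+K+	K	1
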