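# Builtin metabolite library: neutral formula, compound class, positive-mode
# counter-ion, and pathway memberships (PW ids refer to pathways.tsv).
name	formula	compound_class	adduct	pathways
6-Deoxyerythronolide B	C21H38O6	macrolide	+Na+	PW001
Avermectin A2a	C49H76O15	macrolide	+H+	PW001
Avermectin A2a aglycone	C35H52O9	macrolide	+Na+	PW001
Avermectin B2b	C47H72O15	macrolide	+Na+	PW001
Demethyllactenocin	C37H61NO14	macrolide	+NH4+	PW001
Erythronolide B	C21H38O7	macrolide	+K+	PW001
L-Oleandrosyl-oleandolide	C27H46O10	macrolide	+Na+	PW001
(3Z)-Phytochromobilin	C33H36N4O6	bilin	+Na+	PW002
15,16-Dihydrobiliverdin	C33H36N4O6	bilin	+Na+	PW002
Bilirubin	C33H36N4O6	bilin	+Na+	PW002
I-Urobilinogen	C33H44N4O6	bilin	+K+	PW002
19-Hydroxytetrangulol	C19H12O5	polyketide	+K+	PW003
Dehydrorabelomycin	C19H12O5	polyketide	+K+	PW003
(3R)-3-Isopropenyl-6-oxoheptanoate	C10H16O3	terpenoid	+NH4+	PW004
(3S)-3-Isopropenyl-6-oxoheptanoate	C10H16O3	terpenoid	+NH4+	PW004
1,6,6-Trimethyl-2,7-dioxabicyclo[3.2.2]nonan-3-one	C10H16O3	terpenoid	+NH4+	PW005
4,5-Dihydro-5,5-dimethyl-4-(3-oxobutyl)furan-2(3H)-one	C10H16O3	terpenoid	+NH4+	PW005
Alanine	C3H7NO2	amino_acid	+K+	PW010
Arginine	C6H14N4O2	amino_acid	+H+	
Asparagine	C4H8N2O3	amino_acid	+H+	
Aspartate	C4H7NO4	amino_acid	+H+	PW010
Cysteine	C3H7NO2S	amino_acid	+H+	
Glutamate	C5H9NO4	amino_acid	+H+	PW010
Glutamine	C5H10N2O3	amino_acid	+H+	PW010
Glycine	C2H5NO2	amino_acid	+K+	
Histidine	C6H9N3O2	amino_acid	+H+	
Isoleucine	C6H13NO2	amino_acid	+H+	
Leucine	C6H13NO2	amino_acid	+Na+	
Lysine	C6H14N2O2	amino_acid	+H+	
Methionine	C5H11NO2S	amino_acid	+H+	
Phenylalanine	C9H11NO2	amino_acid	+H+	
Proline	C5H9NO2	amino_acid	+H+	
Serine	C3H7NO3	amino_acid	+H+	PW010
Threonine	C4H9NO3	amino_acid	+H+	
Tryptophan	C11H12N2O2	amino_acid	+H+	
Tyrosine	C9H11NO3	amino_acid	+H+	
Valine	C5H11NO2	amino_acid	+H+	
Glucose	C6H12O6	carbohydrate	+Na+	PW006
Sucrose	C12H22O11	carbohydrate	+Na+	
Trehalose	C12H22O11	carbohydrate	+K+	
Ribose	C5H10O5	carbohydrate	+Na+	
Sedoheptulose	C7H14O7	carbohydrate	+Na+	
Mannitol	C6H14O6	carbohydrate	+Na+	
myo-Inositol	C6H12O6	carbohydrate	+K+	
Glucose 6-phosphate	C6H13O9P	carbohydrate	+H+	PW006
Fructose 1,6-bisphosphate	C6H14O12P2	carbohydrate	+H+	PW006
Sucrose 6-phosphate	C12H23O14P	carbohydrate	+H+	
Glycerol 3-phosphate	C3H9O6P	carbohydrate	+H+	PW008
Dihydroxyacetone phosphate	C3H7O6P	carbohydrate	+H+	PW006
3-Phosphoglycerate	C3H7O7P	carbohydrate	+H+	PW006
Phosphoenolpyruvate	C3H5O6P	carbohydrate	+H+	PW006
Ribulose 1,5-bisphosphate	C5H12O11P2	carbohydrate	+H+	
Citrate	C6H8O7	organic_acid	+H+	PW007
Isocitrate	C6H8O7	organic_acid	+Na+	PW007
Malate	C4H6O5	organic_acid	+H+	PW007
Fumarate	C4H4O4	organic_acid	+H+	PW007
Succinate	C4H6O4	organic_acid	+H+	PW007
2-Oxoglutarate	C5H6O5	organic_acid	+H+	PW007
Pyruvate	C3H4O3	organic_acid	+K+	PW006
Lactate	C3H6O3	organic_acid	+K+	
Oxaloacetate	C4H4O5	organic_acid	+H+	PW007
Shikimate	C7H10O5	organic_acid	+H+	
Ascorbate	C6H8O6	organic_acid	+H+	
Adenine	C5H5N5	nucleotide	+H+	PW011
Guanine	C5H5N5O	nucleotide	+H+	PW011
Adenosine	C10H13N5O4	nucleotide	+H+	PW011
Guanosine	C10H13N5O5	nucleotide	+H+	
AMP	C10H14N5O7P	nucleotide	+H+	PW011
ADP	C10H15N5O10P2	nucleotide	+H+	
ATP	C10H16N5O13P3	nucleotide	+H+	
GMP	C10H14N5O8P	nucleotide	+H+	
UMP	C9H13N2O9P	nucleotide	+H+	
CMP	C9H14N3O8P	nucleotide	+H+	
NAD	C21H27N7O14P2	nucleotide	+H+	
NADP	C21H28N7O17P3	nucleotide	+H+	
Uridine	C9H12N2O6	nucleotide	+H+	
Cytidine	C9H13N3O5	nucleotide	+H+	
Inosine	C10H12N4O5	nucleotide	+H+	
Hypoxanthine	C5H4N4O	nucleotide	+H+	PW011
Chlorophyll a	C55H72MgN4O5	pigment	+H+	PW002
Chlorophyll b	C55H70MgN4O6	pigment	+H+	PW002
Chlorophyllide a	C35H34MgN4O5	pigment	+H+	PW002
Pheophytin a	C55H74N4O5	pigment	+H+	
beta-Carotene	C40H56	pigment	+H+	PW012
Zeaxanthin	C40H56O2	pigment	+H+	PW012
Fucoxanthin	C42H58O6	pigment	+Na+	PW012
Peridinin	C39H50O7	pigment	+Na+	PW012
Astaxanthin	C40H52O4	pigment	+H+	
Phytol	C20H40O	pigment	+H+	
Glutathione	C10H17N3O6S	other	+H+	
Choline	C5H13NO	other	+H+	
Glycine betaine	C5H11NO2	other	+H+	
DMSP	C5H10O2S	other	+H+	
Proline betaine	C7H13NO2	other	+H+	
Trigonelline	C7H7NO2	other	+H+	
Spermidine	C7H19N3	other	+H+	
Taurine	C2H7NO3S	other	+H+	
Riboflavin	C17H20N4O6	other	+H+	
Thiamine	C12H16N4OS	other	+H+	
Pyridoxine	C8H11NO3	other	+H+	
Pantothenate	C9H17NO5	other	+H+	
Biotin	C10H16N2O3S	other	+H+	
Folate	C19H19N7O6	other	+H+	
alpha-Tocopherol	C29H50O2	other	+H+	
Ergosterol	C28H44O	other	+H+	
Brassicasterol	C28H46O	other	+H+	
Cholesterol	C27H46O	other	+H+	
Squalene	C30H50	other	+H+	
Dinosterol	C30H52O	other	+H+	
Menaquinone-4	C31H40O2	other	+H+	
Ubiquinone-10	C59H90O4	other	+Na+	
MG(16:0)	C19H38O4	MG	+NH4+	
MG(18:1)	C21H40O4	MG	+NH4+	
MG(18:0)	C21H42O4	MG	+NH4+	
MG(20:5)	C23H36O4	MG	+NH4+	
MG(22:6)	C25H38O4	MG	+NH4+	
MG(14:0)	C17H34O4	MG	+NH4+	
DG(32:0)	C35H68O5	DG	+NH4+	
DG(34:1)	C37H70O5	DG	+NH4+	
DG(36:2)	C39H72O5	DG	+NH4+	
DG(38:6)	C41H68O5	DG	+NH4+	
DG(40:6)	C43H72O5	DG	+NH4+	
DG(30:0)	C33H64O5	DG	+NH4+	
TG(48:0)	C51H98O6	TG	+NH4+	
TG(50:1)	C53H100O6	TG	+NH4+	
TG(52:2)	C55H102O6	TG	+NH4+	
TG(54:3)	C57H104O6	TG	+NH4+	
TG(56:6)	C59H102O6	TG	+NH4+	
TG(46:0)	C49H94O6	TG	+NH4+	
PA(32:0)	C35H69O8P	PA	+Na+	
PA(34:1)	C37H71O8P	PA	+Na+	
PA(36:2)	C39H73O8P	PA	+Na+	
PA(38:6)	C41H69O8P	PA	+Na+	
PA(40:6)	C43H73O8P	PA	+Na+	
PA(30:0)	C33H65O8P	PA	+Na+	
PE(32:0)	C37H74NO8P	PE	+H+	
PE(34:1)	C39H76NO8P	PE	+H+	
PE(36:2)	C41H78NO8P	PE	+H+	
PE(38:6)	C43H74NO8P	PE	+H+	
PE(40:6)	C45H78NO8P	PE	+H+	
PE(30:0)	C35H70NO8P	PE	+H+	
PC(32:0)	C40H80NO8P	PC	+H+	
PC(34:1)	C42H82NO8P	PC	+H+	
PC(36:2)	C44H84NO8P	PC	+H+	
PC(38:6)	C46H80NO8P	PC	+H+	
PC(40:6)	C48H84NO8P	PC	+H+	
PC(30:0)	C38H76NO8P	PC	+H+	
PG(32:0)	C38H75O10P	PG	+Na+	
PG(34:1)	C40H77O10P	PG	+Na+	
PG(36:2)	C42H79O10P	PG	+Na+	
PG(38:6)	C44H75O10P	PG	+Na+	
PG(40:6)	C46H79O10P	PG	+Na+	
PG(30:0)	C36H71O10P	PG	+Na+	
PS(32:0)	C38H74NO10P	PS	+Na+	
PS(34:1)	C40H76NO10P	PS	+Na+	
PS(36:2)	C42H78NO10P	PS	+Na+	
PS(38:6)	C44H74NO10P	PS	+Na+	
PS(40:6)	C46H78NO10P	PS	+Na+	
PS(30:0)	C36H70NO10P	PS	+Na+	
PI(32:0)	C41H79O13P	PI	+K+	
PI(34:1)	C43H81O13P	PI	+K+	
PI(36:2)	C45H83O13P	PI	+K+	
PI(38:6)	C47H79O13P	PI	+K+	
PI(40:6)	C49H83O13P	PI	+K+	
PI(30:0)	C39H75O13P	PI	+K+	
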