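name,formula
glycine,C2H5NO2
alanine,C3H7NO2
serine,C3H7NO3
proline,C5H9NO2
valine,C5H11NO2
betaine,C5H11NO2
threonine,C4H9NO3
cysteine,C3H7NO2S
leucine,C6H13NO2
asparagine,C4H8N2O3
aspartic acid,C4H7NO4
glutamine,C5H10N2O3
glutamic acid,C5H9NO4
lysine,C6H14N2O2
methionine,C5H11NO2S
histidine,C6H9N3O2
phenylalanine,C9H11NO2
arginine,C6H14N4O2
tyrosine,C9H11NO3
tryptophan,C11H12N2O2
creatinine,C4H7N3O
creatine,C4H9N3O2
carnitine,C7H15NO3
taurine,C2H7NO3S
uric acid,C5H4N4O3
hypoxanthine,C5H4N4O
xanthine,C5H4N4O2
caffeine,C8H10N4O2
theobromine,C7H8N4O2
glucose,C6H12O6
citric acid,C6H8O7
succinic acid,C4H6O4
lactic acid,C3H6O3
pyruvic acid,C3H4O3
malic acid,C4H6O5
fumaric acid,C4H4O4
alpha-ketoglutaric acid,C5H6O5
cholesterol,C27H46O
cortisol,C21H30O5
serotonin,C10H12N2O
dopamine,C8H11NO2
epinephrine,C9H13NO3
kynurenine,C10H12N2O3
uridine,C9H12N2O6
inosine,C10H12N4O5
adenosine,C10H13N5O4
nicotinamide,C6H6N2O
pyridoxine,C8H11NO3
riboflavin,C17H20N4O6
pantothenic acid,C9H17NO5
hippuric acid,C9H9NO3
indoxyl sulfate,C8H7NO4S
phenylacetylglutamine,C13H16N2O4
palmitic acid,C16H32O2
oleic acid,C18H34O2
linoleic acid,C18H32O2
arachidonic acid,C20H32O2
glycerophosphocholine,C8H20NO6P
piperine,C17H19NO3
memantine,C12H21N
rivastigmine,C14H22N2O2
donepezil,C24H29NO3
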