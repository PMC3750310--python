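# Static reference: cadmium maximum levels (MLs) in foodstuffs (mg/kg) under
# Chinese national standards, ESFA and WHO. Shipped for context only; no
# computation in this package uses it.
foodstuff,china,esfa,who
"Rice, soybean",0.2,0.2,0.4
"Wheat, bran, germ",0.1,0.2,0.2
"Other cereals",0.1,0.1,0.1
"Peanut",0.5,0.1,0.1
"Vegetables and fruit, excluding leaf",0.05,0.05,0.05
"Stem vegetables, root vegetables and potatoes, excluding celeriac",0.1,0.1,0.1
"Leaf vegetables, fresh herbs, celeriac and common mushroom",0.2,0.2,0.2
"Meat (excluding offal) of bovine animals, sheep, pig, and poultry",0.1,0.05,0.05
"Liver of bovine animals",0.5,0.5,0.5
"Kidney of bovine animals",1,1,1
"Muscle meat of fish, excluding Bonito and bullet tuna",0.1,0.05,0.05-1
"Crustaceans",,0.5,0.05-1
"Bivalve molluscs and Cephalopods",,1,2
"Egg",0.05,,
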