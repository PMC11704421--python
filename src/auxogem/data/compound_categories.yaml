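# Compound -> category table used when grouping gene-compound pairs in
# model-comparison reports. Keys are lower-case display names; anything
# absent maps to "others".
alanine: amino acids
l-alanine: amino acids
arginine: amino acids
l-arginine: amino acids
asparagine: amino acids
l-asparagine: amino acids
aspartate: amino acids
l-aspartate: amino acids
cysteine: amino acids
l-cysteine: amino acids
glutamate: amino acids
l-glutamate: amino acids
glutamine: amino acids
l-glutamine: amino acids
glycine: amino acids
l-glycine: amino acids
histidine: amino acids
l-histidine: amino acids
homoserine: amino acids
l-homoserine: amino acids
isoleucine: amino acids
l-isoleucine: amino acids
leucine: amino acids
l-leucine: amino acids
lysine: amino acids
l-lysine: amino acids
methionine: amino acids
l-methionine: amino acids
phenylalanine: amino acids
l-phenylalanine: amino acids
proline: amino acids
l-proline: amino acids
serine: amino acids
l-serine: amino acids
threonine: amino acids
l-threonine: amino acids
tryptophan: amino acids
l-tryptophan: amino acids
tyrosine: amino acids
l-tyrosine: amino acids
valine: amino acids
l-valine: amino acids
biotin: vitamins
folate: vitamins
inositol: vitamins
myo-inositol: vitamins
nicotinate: vitamins
nicotinic acid: vitamins
pantothenic acid: vitamins
pantothenate: vitamins
pyridoxine: vitamins
riboflavin: vitamins
thiamine: vitamins
adenine: purine and pyrimidine bases
cytosine: purine and pyrimidine bases
guanine: purine and pyrimidine bases
hypoxanthine: purine and pyrimidine bases
thymine: purine and pyrimidine bases
uracil: purine and pyrimidine bases
xanthine: purine and pyrimidine bases
ergosterol: others
heme: others
glutathione: others
choline: others
d-glucosamine: others
spermidine: others
spermine: others
putrescine: others
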