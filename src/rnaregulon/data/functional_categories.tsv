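functional_role	sfc	ofc
B12 biosynthesis	B12 biosynthesis	Coenzyme metabolism
Thiamin biosynthesis	Thiamin biosynthesis	Coenzyme metabolism
Riboflavin biosynthesis	Riboflavin biosynthesis	Coenzyme metabolism
Queuosine biosynthesis	Queuosine biosynthesis	Coenzyme metabolism
Folate biosynthesis	Folate biosynthesis	Coenzyme metabolism
Molybdenum cofactor biosynthesis	Molybdenum cofactor biosynthesis	Coenzyme metabolism
B12 & precursor transporters	B12 & precursor transporters	Coenzyme uptake
Thiamin & precursor transporters	Thiamin & precursor transporters	Coenzyme uptake
Riboflavin transporters	Riboflavin transporters	Coenzyme uptake
Queuosine & precursor transporters	Queuosine & precursor transporters	Coenzyme uptake
Folate transporters	Folate transporters	Coenzyme uptake
Methionine biosynthesis	Methionine biosynthesis	Amino acid metabolism
Methionine & SAM recycling	Methionine & SAM recycling	Amino acid metabolism
Cysteine biosynthesis	Cysteine biosynthesis	Amino acid metabolism
Lysine biosynthesis	Lysine biosynthesis	Amino acid metabolism
Glycine metabolism	Glycine metabolism	Amino acid metabolism
Serine metabolism	Serine metabolism	Amino acid metabolism
Ornithine degradation	Ornithine degradation	Amino acid metabolism
Leucine biosynthesis	Leucine biosynthesis	Amino acid metabolism
Histidine biosynthesis	Histidine biosynthesis	Amino acid metabolism
Threonine biosynthesis	Threonine biosynthesis	Amino acid metabolism
Tryptophan biosynthesis	Tryptophan biosynthesis	Amino acid metabolism
Amino acid biosynthesis	Amino acid biosynthesis	Amino acid metabolism
Methionine transporters	Methionine transporters	Amino acid uptake
Lysine transporters	Lysine transporters	Amino acid uptake
Glycine transporters	Glycine transporters	Amino acid uptake
Histidine transporters	Histidine transporters	Amino acid uptake
Amino acid transporters	Amino acid transporters	Amino acid uptake
Aminosugar biosynthesis	Aminosugar biosynthesis	Secondary metabolism
Citric acid cycle	Citric acid cycle	Secondary metabolism
Urea and agmatine utilization	Urea and agmatine utilization	Secondary metabolism
Cobalt transporters	Cobalt transporters	Metal homeostasis
Molybdenum & tungsten transporters	Molybdenum & tungsten transporters	Metal homeostasis
Magnesium transporters	Magnesium transporters	Metal homeostasis
Potassium transporters	Potassium transporters	Metal homeostasis
Purine metabolism	Purine metabolism	Nucleobase metabolism
Pyrimidine metabolism	Pyrimidine metabolism	Nucleobase metabolism
Purine & precursor transporters	Purine & precursor transporters	Nucleobase uptake
Pyrimidine transporters	Pyrimidine transporters	Nucleobase uptake
Ribosome biogenesis	Ribosome biogenesis	Protein synthesis
Amino acyl-tRNA synthetases	Amino acyl-tRNA synthetases	Protein synthesis
Isozymes of B12-dependent enzymes	Isozymes of B12-dependent enzymes	Miscellaneous
Multidrug resistance transporter	Multidrug resistance transporter	Miscellaneous
Polysaccharide degradation	Polysaccharide degradation	Miscellaneous
Other or unknown functional roles	Other or unknown functional roles	Miscellaneous
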