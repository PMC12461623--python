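name	formula	monoisotopic_mass	source
pyridoxal	C8H9NO3		vitamin B6 vitamer
pyridoxal 5'-phosphate	C8H10NO6P		vitamin B6 vitamer
pyridoxine	C8H11NO3		vitamin B6 vitamer
pyridoxamine	C8H12N2O2		vitamin B6 vitamer
4-pyridoxic acid	C8H9NO4		vitamin B6 catabolite
6-formylpterin	C7H5N5O2		pterin
acetyl-6-formylpterin	C9H7N5O3		pterin
pterin	C6H5N5O		pterin
biopterin	C9H11N5O3		pterin
neopterin	C9H11N5O4		pterin
folic acid	C19H19N7O6		vitamin B9
riboflavin	C17H20N4O6		vitamin B2
lumichrome	C12H10N4O2		riboflavin photoproduct
lumiflavin	C13H12N4O2		riboflavin photoproduct
5-amino-6-D-ribitylaminouracil	C9H16N4O6		riboflavin pathway intermediate
methylglyoxal	C3H4O2		glycolytic byproduct
glyoxal	C2H2O2		glycolytic byproduct
nicotinamide	C6H6N2O		vitamin B3 amide
uracil	C4H4N2O2		nucleobase
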