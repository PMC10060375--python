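# Default enzyme table: saccharification + glycolytic enzymes with apparent
# Michaelis-Menten constants measured free in solution and as displayed on
# quantum dots, oligomeric state, monomer molecular weight, and the estimated
# range of copies that can assemble per nanoparticle type.
#
# kcat in s^-1 per monomer (active site); km in uM; monomer_mw in kDa.
# capacity entries are [min, max] copies per particle for the 4.0 nm QD
# ("qd520"), 9.7 nm QD ("qd600"), 13.4 nm QD ("qd660"), and the
# 19.2 x 17.3 x 2.6 nm nanoplatelet ("npl").
# delta_g is the standard transformed reaction energy in kJ/mol where known.

[Amy]
name = "Amylase"
subunits = 1
monomer_mw = 59.6
free = { kcat = 25.0, km = 213.0 }
bound = { kcat = 24.9, km = 212.0 }
capacity = { qd520 = [4, 10], qd600 = [18, 25], qd660 = [32, 39], npl = [24, 36] }

[Mlt]
name = "Maltase"
subunits = 1
monomer_mw = 74.5
free = { kcat = 0.40, km = 335.0 }
bound = { kcat = 15.3, km = 347.0 }
capacity = { qd520 = [4, 8], qd600 = [16, 21], qd660 = [26, 34], npl = [21, 31] }

[Inv]
name = "Invertase"
subunits = 4
monomer_mw = 47.2
free = { kcat = 0.07, km = 191.0 }
bound = { kcat = 0.26, km = 2504.0 }
capacity = { qd520 = [4, 6], qd600 = [11, 17], qd660 = [18, 29], npl = [14, 24] }

[Glk]
name = "Glucokinase"
subunits = 2
monomer_mw = 36.9
free = { kcat = 2.6, km = 36.0 }
bound = { kcat = 30.7, km = 109.0 }
capacity = { qd520 = [6, 7], qd600 = [19, 29], qd660 = [34, 43], npl = [25, 33] }

[PGI]
name = "Phosphoglucose isomerase"
subunits = 2
monomer_mw = 63.7
free = { kcat = 2481.0, km = 393.0, direction_note = "measured in reverse (fructose-6-phosphate to glucose-6-phosphate)" }
bound = { kcat = 2033.0, km = 398.0, direction_note = "measured in reverse (fructose-6-phosphate to glucose-6-phosphate)" }
capacity = { qd520 = [4, 7], qd600 = [14, 20], qd660 = [22, 34], npl = [17, 23] }

[PFK]
name = "Phosphofructokinase I"
subunits = 4
monomer_mw = 34.6
free = { kcat = 10.1, km = 202.0 }
bound = { kcat = 9.8, km = 203.0 }
capacity = { qd520 = [5, 9], qd600 = [13, 21], qd660 = [22, 36], npl = [17, 24] }

[FBA]
name = "Fructose-bisphosphate aldolase"
subunits = 2
monomer_mw = 41.3
free = { kcat = 6.8, km = 216.0 }
bound = { kcat = 5.7, km = 160.0 }
capacity = { qd520 = [5, 9], qd600 = [18, 27], qd660 = [29, 45], npl = [23, 30] }

[TPI]
name = "Triose phosphate isomerase"
subunits = 2
monomer_mw = 29.1
free = { kcat = 194.0, km = 1717.0 }
bound = { kcat = 225.8, km = 2628.0 }
capacity = { qd520 = [7, 12], qd600 = [23, 32], qd660 = [37, 43], npl = [29, 38] }

[GPD]
name = "Glyceraldehyde-3-phosphate dehydrogenase"
subunits = 4
monomer_mw = 37.7
free = { kcat = 3.2, km = 3494.0 }
bound = { kcat = 9.6, km = 1790.0 }
capacity = { qd520 = [4, 6], qd600 = [13, 20], qd660 = [20, 34], npl = [16, 28] }
delta_g = 15.9

[PGK]
name = "Phosphoglycerate kinase"
subunits = 1
monomer_mw = 43.3
free = { kcat = 18.1, km = 1048.0, direction_note = "measured in reverse (3-phosphoglycerate to 1,3-bisphosphoglycerate)" }
bound = { kcat = 53.1, km = 933.0, direction_note = "measured in reverse (3-phosphoglycerate to 1,3-bisphosphoglycerate)" }
capacity = { qd520 = [5, 12], qd600 = [19, 28], qd660 = [31, 43], npl = [29, 36] }
delta_g = -20.2

[PGM]
name = "Phosphoglycerate mutase"
subunits = 1
monomer_mw = 58.3
free = { kcat = 1.0, km = 3584.0 }
bound = { kcat = 5.3, km = 3344.0 }
capacity = { qd520 = [4, 10], qd600 = [15, 23], qd660 = [25, 36], npl = [24, 37] }

[Eno]
name = "Enolase"
subunits = 2
monomer_mw = 47.8
free = { kcat = 22.9, km = 2040.0 }
bound = { kcat = 31.1, km = 2361.0 }
capacity = { qd520 = [5, 11], qd600 = [16, 25], qd660 = [26, 41], npl = [21, 33] }

[PykA]
name = "Pyruvate kinase II"
subunits = 4
monomer_mw = 53.5
free = { kcat = 277.0, km = 690.0 }
bound = { kcat = 214.0, km = 920.0 }
capacity = { qd520 = [3, 9], qd600 = [10, 19], qd660 = [16, 27], npl = [13, 26] }

[LDH]
name = "Lactate dehydrogenase"
subunits = 4
monomer_mw = 38.7
free = { kcat = 195.5, km = 1470.0 }
bound = { kcat = 202.0, km = 11732.0 }
capacity = { qd520 = [4, 10], qd600 = [12, 27], qd660 = [20, 33], npl = [16, 32] }

[GOx]
# Branch-point competitor consuming glucose; generic literature-scale
# constants for the simulated competition format (not part of the cascade
# kinetic table).
name = "Glucose oxidase"
subunits = 2
monomer_mw = 80.0
free = { kcat = 200.0, km = 25000.0 }
capacity = { qd520 = [1, 4], qd600 = [8, 14], qd660 = [14, 22], npl = [12, 20] }
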