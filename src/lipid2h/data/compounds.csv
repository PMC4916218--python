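compound,kind,n_carbon,branching,n_double_bonds,db_position,h_total_acid,h_nonexch_acid,h_methyl_added,h_fame,h_primer
n-C14:0,fatty_acid,14,normal,0,,28,27,3,30,3
i-C15:0,fatty_acid,15,iso,0,,30,29,3,32,9
a-C15:0,fatty_acid,15,anteiso,0,,30,29,3,32,9
n-C15:0,fatty_acid,15,normal,0,,30,29,3,32,3
i-C16:1 Δ9,fatty_acid,16,iso,1,9,30,29,3,32,7
i-C16:0,fatty_acid,16,iso,0,,32,31,3,34,7
n-C16:1 Δ9,fatty_acid,16,normal,1,9,30,29,3,32,3
n-C16:0,fatty_acid,16,normal,0,,32,31,3,34,3
i-C17:1 Δ9,fatty_acid,17,iso,1,9,32,31,3,34,9
a-C17:1 Δ9,fatty_acid,17,anteiso,1,9,32,31,3,34,9
n-C17:1,fatty_acid,17,normal,1,,32,31,3,34,3
i-C17:0,fatty_acid,17,iso,0,,34,33,3,36,9
a-C17:0,fatty_acid,17,anteiso,0,,34,33,3,36,9
n-C17:0,fatty_acid,17,normal,0,,34,33,3,36,3
n-C18:1 Δ11,fatty_acid,18,normal,1,11,34,33,3,36,3
i-C18:1 Δ11,fatty_acid,18,iso,1,11,34,33,3,36,7
i-C18:0,fatty_acid,18,iso,0,,36,35,3,38,7
n-C18:0,fatty_acid,18,normal,0,,36,35,3,38,3
n-C24:0,fatty_acid,24,normal,0,,48,47,3,50,3
myristic-acid,isotope_standard,14,,0,,28,27,3,30,3
phthalic-acid,isotope_standard,8,,0,,6,4,6,10,0
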