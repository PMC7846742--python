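data_toyhet
_entry.id toyhet
_struct.title 'synthetic fixture with exactly known geometry'
#
loop_
_entity.id
_entity.type
_entity.pdbx_description
1 polymer 'synthetic chain 1'
2 polymer 'synthetic chain 2'
#
loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_seq_one_letter_code
_entity_poly.pdbx_strand_id
1 'polypeptide(L)' GASAGE A
2 'polypeptide(L)' GAKAG B
#
loop_
_entity_poly_seq.entity_id
_entity_poly_seq.num
_entity_poly_seq.mon_id
1 1 GLY
1 2 ALA
1 3 SER
1 4 ALA
1 5 GLY
1 6 GLU
2 1 GLY
2 2 ALA
2 3 LYS
2 4 ALA
2 5 GLY
#
loop_
_struct_asym.id
_struct_asym.entity_id
A 1
B 2
#
loop_
_pdbx_struct_assembly.id
_pdbx_struct_assembly.details
1 author_defined_assembly
#
loop_
_pdbx_struct_assembly_gen.assembly_id
_pdbx_struct_assembly_gen.oper_expression
_pdbx_struct_assembly_gen.asym_id_list
1 '1' A,B
#
loop_
_pdbx_struct_oper_list.id
_pdbx_struct_oper_list.type
_pdbx_struct_oper_list.matrix[1][1]
_pdbx_struct_oper_list.matrix[1][2]
_pdbx_struct_oper_list.matrix[1][3]
_pdbx_struct_oper_list.vector[1]
_pdbx_struct_oper_list.matrix[2][1]
_pdbx_struct_oper_list.matrix[2][2]
_pdbx_struct_oper_list.matrix[2][3]
_pdbx_struct_oper_list.vector[2]
_pdbx_struct_oper_list.matrix[3][1]
_pdbx_struct_oper_list.matrix[3][2]
_pdbx_struct_oper_list.matrix[3][3]
_pdbx_struct_oper_list.vector[3]
1 'identity operation' 1.000000 0.000000 0.000000 0.000000 0.000000 1.000000 0.000000 0.000000 0.000000 0.000000 1.000000 0.000000
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . GLY A 1 1 ? 0.000 0.000 0.000 1.00 10.00 1 A 1
ATOM 2 C CA . GLY A 1 1 ? 1.458 0.000 0.000 1.00 10.00 1 A 1
ATOM 3 C C . GLY A 1 1 ? 2.300 1.100 0.000 1.00 10.00 1 A 1
ATOM 4 O O . GLY A 1 1 ? 2.000 2.250 0.000 1.00 10.00 1 A 1
ATOM 5 N N . ALA A 1 2 ? 3.300 0.000 0.000 1.00 10.00 2 A 1
ATOM 6 C CA . ALA A 1 2 ? 4.758 0.000 0.000 1.00 10.00 2 A 1
ATOM 7 C C . ALA A 1 2 ? 5.600 1.100 0.000 1.00 10.00 2 A 1
ATOM 8 O O . ALA A 1 2 ? 5.300 2.250 0.000 1.00 10.00 2 A 1
ATOM 9 N N . SER A 1 3 ? 6.600 0.000 0.000 1.00 10.00 3 A 1
ATOM 10 C CA . SER A 1 3 ? 8.058 0.000 0.000 1.00 10.00 3 A 1
ATOM 11 C C . SER A 1 3 ? 8.900 1.100 0.000 1.00 10.00 3 A 1
ATOM 12 O O . SER A 1 3 ? 8.600 2.250 0.000 1.00 10.00 3 A 1
ATOM 13 N N . ALA A 1 4 ? 9.900 0.000 0.000 1.00 10.00 4 A 1
ATOM 14 C CA . ALA A 1 4 ? 11.358 0.000 0.000 1.00 10.00 4 A 1
ATOM 15 C C . ALA A 1 4 ? 12.200 1.100 0.000 1.00 10.00 4 A 1
ATOM 16 O O . ALA A 1 4 ? 11.900 2.250 0.000 1.00 10.00 4 A 1
ATOM 17 N N . GLY A 1 5 ? 13.200 0.000 0.000 1.00 10.00 5 A 1
ATOM 18 C CA . GLY A 1 5 ? 14.658 0.000 0.000 1.00 10.00 5 A 1
ATOM 19 C C . GLY A 1 5 ? 15.500 1.100 0.000 1.00 10.00 5 A 1
ATOM 20 O O . GLY A 1 5 ? 15.200 2.250 0.000 1.00 10.00 5 A 1
ATOM 21 N N . GLU A 1 6 ? 16.500 0.000 0.000 1.00 10.00 6 A 1
ATOM 22 C CA . GLU A 1 6 ? 17.958 0.000 0.000 1.00 10.00 6 A 1
ATOM 23 C C . GLU A 1 6 ? 18.800 1.100 0.000 1.00 10.00 6 A 1
ATOM 24 O O . GLU A 1 6 ? 18.500 2.250 0.000 1.00 10.00 6 A 1
ATOM 25 N N . GLY B 2 1 ? 10.600 7.400 1.000 1.00 10.00 1 B 1
ATOM 26 C CA . GLY B 2 1 ? 12.058 7.400 1.000 1.00 10.00 1 B 1
ATOM 27 C C . GLY B 2 1 ? 12.900 8.500 1.000 1.00 10.00 1 B 1
ATOM 28 O O . GLY B 2 1 ? 12.600 9.650 1.000 1.00 10.00 1 B 1
ATOM 29 N N . ALA B 2 2 ? 13.900 7.400 1.000 1.00 10.00 2 B 1
ATOM 30 C CA . ALA B 2 2 ? 15.358 7.400 1.000 1.00 10.00 2 B 1
ATOM 31 C C . ALA B 2 2 ? 16.200 8.500 1.000 1.00 10.00 2 B 1
ATOM 32 O O . ALA B 2 2 ? 15.900 9.650 1.000 1.00 10.00 2 B 1
ATOM 33 N N . LYS B 2 3 ? 17.200 7.400 1.000 1.00 10.00 3 B 1
ATOM 34 C CA . LYS B 2 3 ? 18.658 7.400 1.000 1.00 10.00 3 B 1
ATOM 35 C C . LYS B 2 3 ? 19.500 8.500 1.000 1.00 10.00 3 B 1
ATOM 36 O O . LYS B 2 3 ? 19.200 9.650 1.000 1.00 10.00 3 B 1
ATOM 37 C CB . LYS B 2 3 ? 18.658 5.870 1.000 1.00 10.00 3 B 1
ATOM 38 C CG . LYS B 2 3 ? 19.200 4.800 1.800 1.00 10.00 3 B 1
ATOM 39 C CD . LYS B 2 3 ? 18.700 3.500 2.300 1.00 10.00 3 B 1
ATOM 40 C CE . LYS B 2 3 ? 19.300 2.300 3.000 1.00 10.00 3 B 1
ATOM 41 N NZ . LYS B 2 3 ? 18.800 1.100 3.500 1.00 10.00 3 B 1
ATOM 42 N N . ALA B 2 4 ? 20.500 7.400 1.000 1.00 10.00 4 B 1
ATOM 43 C CA . ALA B 2 4 ? 21.958 7.400 1.000 1.00 10.00 4 B 1
ATOM 44 C C . ALA B 2 4 ? 22.800 8.500 1.000 1.00 10.00 4 B 1
ATOM 45 O O . ALA B 2 4 ? 22.500 9.650 1.000 1.00 10.00 4 B 1
ATOM 46 N N . GLY B 2 5 ? 23.800 7.400 1.000 1.00 10.00 5 B 1
ATOM 47 C CA . GLY B 2 5 ? 25.258 7.400 1.000 1.00 10.00 5 B 1
ATOM 48 C C . GLY B 2 5 ? 26.100 8.500 1.000 1.00 10.00 5 B 1
ATOM 49 O O . GLY B 2 5 ? 25.800 9.650 1.000 1.00 10.00 5 B 1
#
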