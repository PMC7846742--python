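data_toyhomo
_entry.id toyhomo
_struct.title 'synthetic fixture with exactly known geometry'
#
loop_
_entity.id
_entity.type
_entity.pdbx_description
1 polymer 'synthetic chain 1'
#
loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_seq_one_letter_code
_entity_poly.pdbx_strand_id
1 'polypeptide(L)' GAKAGE A
#
loop_
_entity_poly_seq.entity_id
_entity_poly_seq.num
_entity_poly_seq.mon_id
1 1 GLY
1 2 ALA
1 3 LYS
1 4 ALA
1 5 GLY
1 6 GLU
#
loop_
_struct_asym.id
_struct_asym.entity_id
A 1
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
1 '1,2' A
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
2 'point symmetry operation' -1.000000 0.000000 0.000000 27.000000 0.000000 -1.000000 0.000000 1.800000 0.000000 0.000000 1.000000 -2.500000
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
ATOM 9 N N . LYS A 1 3 ? 6.600 0.000 0.000 1.00 10.00 3 A 1
ATOM 10 C CA . LYS A 1 3 ? 8.058 0.000 0.000 1.00 10.00 3 A 1
ATOM 11 C C . LYS A 1 3 ? 8.900 1.100 0.000 1.00 10.00 3 A 1
ATOM 12 O O . LYS A 1 3 ? 8.600 2.250 0.000 1.00 10.00 3 A 1
ATOM 13 C CB . LYS A 1 3 ? 8.058 -1.530 0.000 1.00 10.00 3 A 1
ATOM 14 C CG . LYS A 1 3 ? 8.600 -2.600 0.800 1.00 10.00 3 A 1
ATOM 15 C CD . LYS A 1 3 ? 8.100 -3.900 1.300 1.00 10.00 3 A 1
ATOM 16 C CE . LYS A 1 3 ? 8.700 -5.100 2.000 1.00 10.00 3 A 1
ATOM 17 N NZ . LYS A 1 3 ? 8.200 -6.300 2.500 1.00 10.00 3 A 1
ATOM 18 N N . ALA A 1 4 ? 9.900 0.000 0.000 1.00 10.00 4 A 1
ATOM 19 C CA . ALA A 1 4 ? 11.358 0.000 0.000 1.00 10.00 4 A 1
ATOM 20 C C . ALA A 1 4 ? 12.200 1.100 0.000 1.00 10.00 4 A 1
ATOM 21 O O . ALA A 1 4 ? 11.900 2.250 0.000 1.00 10.00 4 A 1
ATOM 22 N N . GLY A 1 5 ? 13.200 0.000 0.000 1.00 10.00 5 A 1
ATOM 23 C CA . GLY A 1 5 ? 14.658 0.000 0.000 1.00 10.00 5 A 1
ATOM 24 C C . GLY A 1 5 ? 15.500 1.100 0.000 1.00 10.00 5 A 1
ATOM 25 O O . GLY A 1 5 ? 15.200 2.250 0.000 1.00 10.00 5 A 1
ATOM 26 N N . GLU A 1 6 ? 16.500 0.000 0.000 1.00 10.00 6 A 1
ATOM 27 C CA . GLU A 1 6 ? 17.958 0.000 0.000 1.00 10.00 6 A 1
ATOM 28 C C . GLU A 1 6 ? 18.800 1.100 0.000 1.00 10.00 6 A 1
ATOM 29 O O . GLU A 1 6 ? 18.500 2.250 0.000 1.00 10.00 6 A 1
#
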