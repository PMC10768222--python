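name,level,group,voxel_agg,residue_agg,dtype,source
H,atom,atom_type_onehot,max,none,u1,autodock_type
HD,atom,atom_type_onehot,max,none,u1,autodock_type
HS,atom,atom_type_onehot,max,none,u1,autodock_type
C,atom,atom_type_onehot,max,none,u1,autodock_type
A,atom,atom_type_onehot,max,none,u1,autodock_type
N,atom,atom_type_onehot,max,none,u1,autodock_type
NA,atom,atom_type_onehot,max,none,u1,autodock_type
NS,atom,atom_type_onehot,max,none,u1,autodock_type
OA,atom,atom_type_onehot,max,none,u1,autodock_type
OS,atom,atom_type_onehot,max,none,u1,autodock_type
F,atom,atom_type_onehot,max,none,u1,autodock_type
MG,atom,atom_type_onehot,max,none,u1,autodock_type
P,atom,atom_type_onehot,max,none,u1,autodock_type
SA,atom,atom_type_onehot,max,none,u1,autodock_type
S,atom,atom_type_onehot,max,none,u1,autodock_type
CL,atom,atom_type_onehot,max,none,u1,autodock_type
CA,atom,atom_type_onehot,max,none,u1,autodock_type
MN,atom,atom_type_onehot,max,none,u1,autodock_type
FE,atom,atom_type_onehot,max,none,u1,autodock_type
ZN,atom,atom_type_onehot,max,none,u1,autodock_type
BR,atom,atom_type_onehot,max,none,u1,autodock_type
I,atom,atom_type_onehot,max,none,u1,autodock_type
Unk_atom,atom,atom_type_onehot,max,none,u1,autodock_type
C_elem,atom,element_onehot,max,none,u1,pdb_element
N_elem,atom,element_onehot,max,none,u1,pdb_element
O_elem,atom,element_onehot,max,none,u1,pdb_element
S_elem,atom,element_onehot,max,none,u1,pdb_element
H_elem,atom,element_onehot,max,none,u1,pdb_element
F_elem,atom,element_onehot,max,none,u1,pdb_element
MG_elem,atom,element_onehot,max,none,u1,pdb_element
P_elem,atom,element_onehot,max,none,u1,pdb_element
CL_elem,atom,element_onehot,max,none,u1,pdb_element
CA_elem,atom,element_onehot,max,none,u1,pdb_element
MN_elem,atom,element_onehot,max,none,u1,pdb_element
FE_elem,atom,element_onehot,max,none,u1,pdb_element
ZN_elem,atom,element_onehot,max,none,u1,pdb_element
BR_elem,atom,element_onehot,max,none,u1,pdb_element
I_elem,atom,element_onehot,max,none,u1,pdb_element
Unk_elem,atom,element_onehot,max,none,u1,pdb_element
vdw,atom,continuous,mean,mean,f4,vdw_table
charge,atom,continuous,mean,sum,f4,charge_provider
electrostatic_potential,atom,continuous,mean,sum,f4,coulomb_ddd
cx,atom,continuous,mean,mean,f4,concavity_cx
hydrophobicity,residue,continuous,mean,map_down,f4,kyte_doolittle
biological_hydrophobicity,residue,continuous,mean,map_down,f4,biological_scale
octanol_hydrophobicity,residue,continuous,mean,map_down,f4,octanol_scale
atom_asa,atom,continuous,mean,none,f4,shrake_rupley
residue_rasa,residue,continuous,mean,map_down,f4,shrake_rupley
ALA,residue,residue_onehot,max,map_down,u1,pdb_residue
CYS,residue,residue_onehot,max,map_down,u1,pdb_residue
ASP,residue,residue_onehot,max,map_down,u1,pdb_residue
GLU,residue,residue_onehot,max,map_down,u1,pdb_residue
PHE,residue,residue_onehot,max,map_down,u1,pdb_residue
GLY,residue,residue_onehot,max,map_down,u1,pdb_residue
HIS,residue,residue_onehot,max,map_down,u1,pdb_residue
ILE,residue,residue_onehot,max,map_down,u1,pdb_residue
LYS,residue,residue_onehot,max,map_down,u1,pdb_residue
LEU,residue,residue_onehot,max,map_down,u1,pdb_residue
MET,residue,residue_onehot,max,map_down,u1,pdb_residue
ASN,residue,residue_onehot,max,map_down,u1,pdb_residue
PRO,residue,residue_onehot,max,map_down,u1,pdb_residue
GLN,residue,residue_onehot,max,map_down,u1,pdb_residue
ARG,residue,residue_onehot,max,map_down,u1,pdb_residue
SER,residue,residue_onehot,max,map_down,u1,pdb_residue
THR,residue,residue_onehot,max,map_down,u1,pdb_residue
VAL,residue,residue_onehot,max,map_down,u1,pdb_residue
TRP,residue,residue_onehot,max,map_down,u1,pdb_residue
TYR,residue,residue_onehot,max,map_down,u1,pdb_residue
Unk_residue,residue,residue_onehot,max,map_down,u1,pdb_residue
phi,residue,continuous,mean,map_down,f4,torsions
phi_sin,residue,continuous,mean,map_down,f4,torsions
phi_cos,residue,continuous,mean,map_down,f4,torsions
psi,residue,continuous,mean,map_down,f4,torsions
psi_sin,residue,continuous,mean,map_down,f4,torsions
psi_cos,residue,continuous,mean,map_down,f4,torsions
phi_defined,residue,mask,max,map_down,u1,torsions
psi_defined,residue,mask,max,map_down,u1,torsions
is_helix,residue,ss3_onehot,max,map_down,u1,secondary_structure
is_sheet,residue,ss3_onehot,max,map_down,u1,secondary_structure
Unk_SS,residue,ss3_onehot,max,map_down,u1,secondary_structure
is_regular_helix,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_beta_bridge,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_extended_strand,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_310_helix,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_pi_helix,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_hbond_turn,residue,ss8_onehot,max,map_down,u1,secondary_structure
is_bend,residue,ss8_onehot,max,map_down,u1,secondary_structure
no_ss,residue,ss8_onehot,max,map_down,u1,secondary_structure
hydrophobic_atom,atom,autodock_flag,max,none,u1,autodock_flags
aromatic_atom,atom,autodock_flag,max,none,u1,autodock_flags
hbond_acceptor,atom,autodock_flag,max,none,u1,autodock_flags
hbond_donor,atom,autodock_flag,max,none,u1,autodock_flags
metal,atom,autodock_flag,max,none,u1,autodock_flags
eppic_entropy,residue,continuous,min,map_down,f4,sequence_entropy
neg_charge,atom,boolean,max,none,u1,discretize
pos_charge,atom,boolean,max,none,u1,discretize
is_electronegative,atom,boolean,max,none,u1,discretize
is_concave,atom,boolean,max,none,u1,discretize
is_hydrophobic,residue,boolean,max,map_down,u1,discretize
residue_buried,residue,boolean,max,map_down,u1,discretize
is_conserved,residue,boolean,max,map_down,u1,discretize
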