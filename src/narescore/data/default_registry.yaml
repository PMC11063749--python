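# Default interaction-type registry.
#
# Maps raw receptor atoms (residue name + atom name) and raw ligand SYBYL
# types to the closed sets of 26 receptor and 24 ligand interaction labels
# used to index distance-fingerprint features (26 x 24 = 624 pairs).
#
# The exact published groupings are not fully enumerable from public text;
# this registry is an informed reconstruction that reproduces the label
# cardinalities and the documented rules (backbone -> N, thymine grouped
# with uracil, modified-region atoms -> OTH by element, monoatomic ions ->
# Metal, rare ligand types binned by chemical similarity).  Replace or edit
# this file (CLI: --registry) to change the typing without code changes.

# residue name -> canonical nucleobase class (A, C, G, U).  Covers RNA, DNA
# and a starter set of common modified residues; thymine maps to the U class.
nucleobase_alias:
  "A": A
  "C": C
  "G": G
  "U": U
  "DA": A
  "DC": C
  "DG": G
  "DT": U
  "DU": U
  "T": U
  "I": G
  "DI": G
  "PSU": U
  "H2U": U
  "5MU": U
  "4SU": U
  "OMU": U
  "1MA": A
  "MA6": A
  "OMA": A
  "5MC": C
  "OMC": C
  "2MG": G
  "7MG": G
  "M2G": G
  "OMG": G
  "YG": G

# backbone atom names (ribose + phosphate) -> SYBYL group; these atoms get
# residue class N regardless of the residue they sit in.
backbone_atoms:
  "P": P.3
  "OP1": O.2
  "OP2": O.2
  "OP3": O.2
  "O1P": O.2
  "O2P": O.2
  "O3P": O.2
  "O5'": O.3
  "C5'": C.3
  "C4'": C.3
  "O4'": O.3
  "C3'": C.3
  "O3'": O.3
  "C2'": C.3
  "O2'": O.3
  "C1'": C.3

# canonical base atom names per nucleobase class -> SYBYL group.  An atom of
# an aliased (modified) residue whose name is NOT in the parent base's set is
# a modified-region atom and falls back to class OTH.
base_atoms:
  A:
    "N9": N.ar
    "C8": C.ar
    "N7": N.ar
    "C5": C.ar
    "C6": C.ar
    "N6": N.pl3
    "N1": N.ar
    "C2": C.ar
    "N3": N.ar
    "C4": C.ar
  G:
    "N9": N.ar
    "C8": C.ar
    "N7": N.ar
    "C5": C.ar
    "C6": C.ar
    "O6": O.2
    "N1": N.ar
    "C2": C.ar
    "N2": N.pl3
    "N3": N.ar
    "C4": C.ar
  C:
    "N1": N.ar
    "C2": C.ar
    "O2": O.2
    "N3": N.ar
    "C4": C.ar
    "N4": N.pl3
    "C5": C.ar
    "C6": C.ar
  U:
    "N1": N.ar
    "C2": C.ar
    "O2": O.2
    "N3": N.ar
    "C4": C.ar
    "O4": O.2
    "C5": C.ar
    "C6": C.ar
    "C7": C.3     # thymine methyl (modern nomenclature)
    "C5M": C.3    # thymine methyl (legacy nomenclature)

# element -> OTH-class label for modified-region / unrecognised receptor
# atoms ("other" elements share one sparse bin).
oth_element_groups:
  "C": OTH_C
  "N": OTH_N
  "O": OTH_O
  "P": OTH_P
  "S": OTH_S
  default: OTH_X

# monoatomic-ion / metal elements (upper-case symbols).  Receptor side ->
# class Metal; ligand side -> the ligand Metal group (organometallics).
metal_elements:
  [LI, BE, NA, MG, AL, K, CA, SC, TI, V, CR, MN, FE, CO, NI, CU, ZN, GA,
   RB, SR, Y, ZR, MO, RU, RH, PD, AG, CD, IN, SN, CS, BA, W, RE, OS, IR,
   PT, AU, HG, TL, PB]

# raw ligand SYBYL type -> one of the 24 ligand group labels (rare types
# binned with their closest chemistry).
ligand_sybyl_grouping:
  "C.1": C.1
  "C.2": C.2
  "C.3": C.3
  "C.ar": C.ar
  "C.cat": C.cat
  "N.1": N.1
  "N.2": N.2
  "N.3": N.3
  "N.4": N.4
  "N.am": N.am
  "N.ar": N.ar
  "N.pl3": N.pl3
  "O.2": O.2
  "O.3": O.3
  "O.co2": O.co2
  "O.spc": O.3
  "O.t3p": O.3
  "P.3": P.3
  "S.3": S.3
  "S.2": S.3
  "S.o": S.o2
  "S.o2": S.o2
  "F": F
  "Cl": Cl
  "Br": Br
  "I": I
  "Se": Se
  "Metal": Metal

# closed, ordered label sets indexing the feature columns.
receptor_labels:
  [A_C.ar, A_N.ar, A_N.pl3,
   C_C.ar, C_N.ar, C_N.pl3, C_O.2,
   G_C.ar, G_N.ar, G_N.pl3, G_O.2,
   U_C.3, U_C.ar, U_N.ar, U_O.2,
   N_C.3, N_O.2, N_O.3, N_P.3,
   OTH_C, OTH_N, OTH_O, OTH_P, OTH_S, OTH_X,
   Metal]

ligand_labels:
  [C.1, C.2, C.3, C.ar, C.cat,
   N.1, N.2, N.3, N.4, N.am, N.ar, N.pl3,
   O.2, O.3, O.co2,
   P.3, S.3, S.o2,
   F, Cl, Br, I, Se,
   Metal]
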