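abbreviation,name,formula,polarity,derivatization,n_obha_sites,fragment_kind,fragment_formula,q1,q3_list,ce_list,rt,method_tag,note
K,Lysine,C6H14N2O2,positive,none,0,none,,147.0,84.1,16,2.72,pos_underivatized,isobaric with glutamine; resolved by RT
H,Histidine,C6H9N3O2,positive,none,0,loss,CH2O2,156.0,110.0,12,2.76,pos_underivatized,
R,Arginine,C6H14N4O2,positive,none,0,none,,175.2,60.0,14,2.79,pos_underivatized,
S,Serine,C3H7NO3,positive,none,0,loss,CH2O2,106.0,60.0,13,3.27,pos_underivatized,
A,Alanine,C3H7NO2,positive,none,0,loss,CH2O2,90.0,44.0,11,3.30,pos_underivatized,
N,Asparagine,C4H8N2O3,positive,none,0,none,,133.1,74.0,15,3.30,pos_underivatized,
Q,Glutamine,C5H10N2O3,positive,none,0,none,,147.0,84.1,16,3.36,pos_underivatized,isobaric with lysine; resolved by RT
T,Threonine,C4H9NO3,positive,none,0,none,,120.0,56.0,30,3.39,pos_underivatized,
D,Aspartate,C4H7NO4,positive,none,0,none,,134.1,74.0,15,3.46,pos_underivatized,
E,Glutamate,C5H9NO4,positive,none,0,none,,148.1,84.1,16,3.48,pos_underivatized,
C,Cysteine,C3H7NO2S,positive,none,0,none,,122.2,59.0,27,3.58,pos_underivatized,
P,Proline,C5H9NO2,positive,none,0,loss,CH2O2,116.0,70.0,11,3.84,pos_underivatized,
V,Valine,C5H11NO2,positive,none,0,loss,CH2O2,118.0,72.0,15,4.35,pos_underivatized,
M,Methionine,C5H11NO2S,positive,none,0,none,,150.1,56.0,15,5.30,pos_underivatized,
I,Isoleucine,C6H13NO2,positive,none,0,loss,CH2O2,132.0,86.0,11,6.53,pos_underivatized,isobaric with leucine; resolved by RT
L,Leucine,C6H13NO2,positive,none,0,loss,CH2O2,132.0,86.0,11,6.90,pos_underivatized,isobaric with isoleucine; resolved by RT
Y,Tyrosine,C9H11NO3,positive,none,0,loss,CH2O2,182.2,136.0,14,7.04,pos_underivatized,
F,Phenylalanine,C9H11NO2,positive,none,0,loss,CH2O2,166.0,120.0,25,9.12,pos_underivatized,
W,Tryptophan,C11H12N2O2,positive,none,0,none,,205.0,146.0,16,10.14,pos_underivatized,
AMP,Adenosine 5'-monophosphate,C10H14N5O7P,positive,none,0,ion,C5H5N5,348,136,21,6.62,pos_underivatized,release of nitrogen base (adenine) monitored
GMP,Guanosine 5'-monophosphate,C10H14N5O8P,positive,none,0,ion,C5H5N5O,364,152,18,7.96,pos_underivatized,release of nitrogen base (guanine) monitored
CMP,Cytidine 5'-monophosphate,C9H14N3O8P,positive,none,0,ion,C4H5N3O,324,112,21,4.57,pos_underivatized,release of nitrogen base (cytosine) monitored
UMP,Uridine 5'-monophosphate,C9H13N2O9P,positive,none,0,ion,C4H4N2O2,325,113,21,7.83,pos_underivatized,release of nitrogen base (uracil) monitored
SAM,S-Adenosyl methionine,C15H22N6O5S,positive,none,0,none,,399,250,13,2.86,pos_underivatized,
SAH,S-Adenosyl homocysteine,C14H20N6O5S,positive,none,0,ion,C5H5N5,385,136,19,6.92,pos_underivatized,adenine product ion
GSH,Glutathione reduced,C10H17N3O6S,positive,none,0,none,,308,162,17,6.05,pos_underivatized,
GSSG,Glutathione oxidized,C20H32N6O12S2,positive,none,0,none,,613,231,34,7.45,pos_underivatized,
D_neg,Aspartate (negative mode),C4H7NO4,negative,none,0,loss,CO2,131.9,88.1,-20,3.26,neg_underivatized,monitors fate of aspartate into gluconeogenesis
Tre,Trehalose,C12H22O11,negative,none,0,ion,C6H12O6,341.3,179.3,-17,4.00,neg_underivatized,glycosidic cleavage to deprotonated hexose
G6P,Glucose 6-phosphate,C6H13O9P,negative,none,0,ion,H3PO4,259,97,-20,3.14,neg_underivatized,phosphate reporter; RTs of sugar phosphates nearly coincide
G3P,Glyceraldehyde 3-phosphate,C3H7O6P,negative,none,0,ion,H3PO4,169,97,-20,3.17,neg_underivatized,phosphate reporter
3PG,3-Phosphoglycerate,C3H7O7P,negative,none,0,ion,H3PO4,185,97,-20,3.02,neg_underivatized,phosphate reporter
R5P,Ribose 5-phosphate,C5H11O8P,negative,none,0,ion,H3PO4,229,97,-20,3.20,neg_underivatized,phosphate reporter
S7P,Sedoheptulose 7-phosphate,C7H15O10P,negative,none,0,ion,H3PO4,289,97,-20,3.15,neg_underivatized,phosphate reporter
Pyr,Pyruvate,C3H4O3,positive,OBHA,2,none,,299,181,15,9.43,obha_gradient1,second standard peak (Pyr*) of unclear identity
Lac,Lactate,C3H6O3,positive,OBHA,1,ion,C7H6,196,91.2;124;65.2,25;15;40,6.71,obha_gradient1,benzyl/tropylium reporter
MG,Methylglyoxal,C3H4O2,positive,OBHA,2,ion,C7H6,283,91.2;158.2,25;14,11.30,obha_gradient1,benzyl/tropylium reporter
Cit,Citrate,C6H8O7,positive,OBHA,3,ion,C7H6,508,91.2;385,25;7,8.70,obha_gradient1,benzyl/tropylium reporter
2-KG,2-Ketoglutarate,C5H6O5,positive,OBHA,3,ion,C7H6,462,91.2;339,25;11,9.34,obha_gradient1,benzyl/tropylium reporter
OAA,Oxaloacetate,C4H4O5,positive,OBHA,3,none,,448,325,10,9.20,obha_gradient1,
G_obha,Glycine (OBHA),C2H5NO2,positive,OBHA,1,none,,181,166,17,8.9,obha_gradient2,
D_obha,Aspartate (OBHA),C4H7NO4,positive,OBHA,2,ion,C7H6,344,91.2,32,5.58,obha_gradient2,benzyl/tropylium reporter
E_obha,Glutamate (OBHA),C5H9NO4,positive,OBHA,1,ion,C7H6,253,91.2,21,11.9,obha_gradient2,mono-derivatized despite two carboxyls
Q_obha,Glutamine (OBHA),C5H10N2O3,positive,OBHA,1,ion,C7H6,251,91.2,34,8.04,obha_gradient2,printed Q1 251 is one below the computed mono-derivatized 252; possible in-source ammonia loss or typo
Suc,Succinate,C4H6O4,positive,OBHA,2,ion,C7H6,329,206;91.2,15;34,8.60,obha_gradient2,benzyl/tropylium reporter
Fum,Fumarate,C4H4O4,positive,OBHA,2,ion,C7H6,327,204;91.2,15;34,9.25,obha_gradient2,benzyl/tropylium reporter
Mal,Malate,C4H6O5,positive,OBHA,2,ion,C7H6,345,91.2,33,8.07,obha_gradient2,benzyl/tropylium reporter
Glyox,Glyoxalate,C2H2O3,positive,OBHA,2,ion,C7H6,285,65.1;91.2,51;33,9.37,obha_gradient2,benzyl/tropylium reporter
2-HG,2-Hydroxyglutarate,C5H8O5,positive,OBHA,2,ion,C7H6,359,91.2,35,7.8,obha_gradient2,benzyl/tropylium reporter
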