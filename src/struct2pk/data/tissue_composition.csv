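# Rat tissue composition for tissue-to-plasma partition coefficient models.
# Fractional volumes per mL tissue, assembled from the published composition
# tables of Rodgers & Rowland (J Pharm Sci 2005 94:1259; 2006 95:1238) and
# Poulin & Theil (J Pharm Sci 2002 91:129); albumin ratios from Rodgers &
# Rowland 2006; total protein fractions from standard tissue-composition
# compilations.
# f_water_ec / f_water_ic: extracellular / intracellular water fraction
# f_nl: neutral lipid fraction; f_np: neutral phospholipid fraction
# ap_mg_per_g: acidic phospholipid content, mg per g tissue
# albumin_ratio: tissue-to-plasma albumin concentration ratio
# f_protein: total protein fraction (used by lumped-protein methods)
# The plasma row carries plasma water and lipid fractions; its albumin_ratio
# is 1 by definition.
tissue,f_water_ec,f_water_ic,f_nl,f_np,ap_mg_per_g,albumin_ratio,f_protein
adipose,0.135,0.017,0.840,0.0016,0.40,0.049,0.049
bone,0.100,0.346,0.017,0.0017,0.67,0.100,0.185
brain,0.162,0.620,0.039,0.0015,0.40,0.048,0.080
gut,0.282,0.475,0.038,0.0125,2.41,0.158,0.146
heart,0.320,0.456,0.014,0.0111,2.25,0.157,0.157
kidney,0.273,0.483,0.012,0.0242,5.03,0.130,0.166
liver,0.161,0.573,0.014,0.0240,4.56,0.086,0.203
lung,0.336,0.446,0.022,0.0128,3.91,0.212,0.148
muscle,0.118,0.630,0.010,0.0072,1.53,0.064,0.190
skin,0.382,0.291,0.060,0.0044,1.32,0.277,0.300
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097,0.180
plasma,0.945,0.0,0.0023,0.0013,0.0,1.0,0.070
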