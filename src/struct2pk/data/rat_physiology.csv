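# Rat whole-body physiology (250 g animal), per kg body weight.
# Organ volumes and regional blood flows assembled from standard reference
# compilations of rodent physiology (Brown et al. 1997, Physiological
# parameter values for PBPK models; Davies & Morris 1993, Pharm Res 10:1093).
# Flows are arranged so that hepatic inflow (hepatic artery + gut + spleen)
# equals 55.2 mL/min/kg and the lung receives the full cardiac output
# (273.6 mL/min/kg, the sum of all systemic organ flows).
# volume_ml_per_kg: tissue volume, mL per kg body weight (density ~1 g/mL)
# flow_ml_per_min_kg: blood flow, mL/min per kg body weight; for liver this
#   is the hepatic artery only, portal inflow arrives via gut and spleen.
tissue,volume_ml_per_kg,flow_ml_per_min_kg
adipose,76.0,20.7
bone,41.5,36.1
brain,5.7,5.9
gut,27.0,39.8
heart,3.3,14.5
kidney,7.3,41.7
liver,40.0,6.2
lung,5.0,273.6
muscle,404.0,82.3
skin,190.0,17.2
spleen,2.0,9.2
arterial_blood,24.7,
venous_blood,49.3,
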