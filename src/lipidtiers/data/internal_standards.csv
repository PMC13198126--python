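# Internal-standard cocktail for organic-acid quantification.
# spike concentrations and 50 uL spike volume follow the extraction recipe;
# mw_g_mol is the labelled-compound molecular weight used to convert the
# spiked mass to pmol. "rule" routes analytes to their standard:
#   scfa              C2-C6 fatty acids
#   mcfa              C7-C12 fatty acids
#   saturated_long    >= C13 fatty acids with 0 double bonds
#   unsaturated_long  >= C13 fatty acids with >= 1 double bond
#   polar             matched per-analyte via the panel's polar_is_id column
is_id,rule,conc_ug_per_ml,spike_volume_ul,mw_g_mol
"butyric-2,2-d2-acid",scfa,10,50,90.12
octanoic acid-1-13C,mcfa,1,50,145.20
d31-FA-C16:0,saturated_long,5,50,287.62
d8-FA-C20:4,unsaturated_long,5,50,312.52
"2,2,3,3-d4-succinic acid",polar,5,50,122.11
d4-fumaric acid,polar,10,50,120.10
"2,2,4,4-d4-citric acid",polar,20,50,196.15
"2,3,3-d3-malic acid",polar,5,50,137.11
d3-pyruvic acid,polar,10,50,91.08
d3-lactic acid,polar,20,50,93.10
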