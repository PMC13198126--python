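# Synthetic reconstruction of the branch-C organic-acid panel:
# 7 SCFA, 6 MCFA, 38 LCFA, 50 VLCFA, 15 polar carboxylic acids (116 total).
# Chain-resolved analytes carry a parseable shorthand; branched-chain
# isomers share a shorthand and are distinguished by analyte_id.
analyte_id,kind,shorthand,mw_g_mol,polar_is_id
FA 2:0,fatty acid,FA 2:0,,
FA 3:0,fatty acid,FA 3:0,,
FA 4:0,fatty acid,FA 4:0,,
FA 5:0,fatty acid,FA 5:0,,
FA 6:0,fatty acid,FA 6:0,,
FA 4:0 iso,fatty acid,FA 4:0,,
FA 5:0 iso,fatty acid,FA 5:0,,
FA 7:0,fatty acid,FA 7:0,,
FA 8:0,fatty acid,FA 8:0,,
FA 10:0,fatty acid,FA 10:0,,
FA 12:0,fatty acid,FA 12:0,,
FA 14:0,fatty acid,FA 14:0,,
FA 14:2,fatty acid,FA 14:2,,
FA 15:0,fatty acid,FA 15:0,,
FA 15:1,fatty acid,FA 15:1,,
FA 15:2,fatty acid,FA 15:2,,
FA 16:0,fatty acid,FA 16:0,,
FA 16:1 n-9,fatty acid,FA 16:1 n-9,,
FA 16:1 n-7,fatty acid,FA 16:1 n-7,,
FA 16:2,fatty acid,FA 16:2,,
FA 16:3,fatty acid,FA 16:3,,
FA 16:4,fatty acid,FA 16:4,,
FA 17:0,fatty acid,FA 17:0,,
FA 17:1,fatty acid,FA 17:1,,
FA 17:2,fatty acid,FA 17:2,,
FA 18:0,fatty acid,FA 18:0,,
FA 18:1 n-9,fatty acid,FA 18:1 n-9,,
FA 18:1 n-7,fatty acid,FA 18:1 n-7,,
FA 18:2,fatty acid,FA 18:2,,
FA 18:3 n-3,fatty acid,FA 18:3 n-3,,
FA 18:3 n-6,fatty acid,FA 18:3 n-6,,
FA 18:3 n-9,fatty acid,FA 18:3 n-9,,
FA 18:4,fatty acid,FA 18:4,,
FA 19:0,fatty acid,FA 19:0,,
FA 19:1,fatty acid,FA 19:1,,
FA 19:2,fatty acid,FA 19:2,,
FA 19:3,fatty acid,FA 19:3,,
FA 20:0,fatty acid,FA 20:0,,
FA 20:1,fatty acid,FA 20:1,,
FA 20:2,fatty acid,FA 20:2,,
FA 20:3 n-3,fatty acid,FA 20:3 n-3,,
FA 20:3 n-6,fatty acid,FA 20:3 n-6,,
FA 20:3 n-9,fatty acid,FA 20:3 n-9,,
FA 20:4 n-6,fatty acid,FA 20:4 n-6,,
FA 20:4 n-3,fatty acid,FA 20:4 n-3,,
FA 20:5,fatty acid,FA 20:5,,
FA 21:0,fatty acid,FA 21:0,,
FA 21:1,fatty acid,FA 21:1,,
FA 21:2,fatty acid,FA 21:2,,
FA 21:3,fatty acid,FA 21:3,,
FA 21:4,fatty acid,FA 21:4,,
FA 22:0,fatty acid,FA 22:0,,
FA 22:1,fatty acid,FA 22:1,,
FA 22:2,fatty acid,FA 22:2,,
FA 22:3,fatty acid,FA 22:3,,
FA 22:4,fatty acid,FA 22:4,,
FA 22:5 n-3,fatty acid,FA 22:5 n-3,,
FA 22:5 n-6,fatty acid,FA 22:5 n-6,,
FA 22:6,fatty acid,FA 22:6,,
FA 23:0,fatty acid,FA 23:0,,
FA 23:1,fatty acid,FA 23:1,,
FA 24:0,fatty acid,FA 24:0,,
FA 24:1,fatty acid,FA 24:1,,
FA 24:2,fatty acid,FA 24:2,,
FA 24:3,fatty acid,FA 24:3,,
FA 24:4,fatty acid,FA 24:4,,
FA 24:5,fatty acid,FA 24:5,,
FA 24:6,fatty acid,FA 24:6,,
FA 25:0,fatty acid,FA 25:0,,
FA 25:1,fatty acid,FA 25:1,,
FA 26:0,fatty acid,FA 26:0,,
FA 26:1,fatty acid,FA 26:1,,
FA 26:2,fatty acid,FA 26:2,,
FA 26:3,fatty acid,FA 26:3,,
FA 26:4,fatty acid,FA 26:4,,
FA 26:5,fatty acid,FA 26:5,,
FA 26:6,fatty acid,FA 26:6,,
FA 27:0,fatty acid,FA 27:0,,
FA 28:0,fatty acid,FA 28:0,,
FA 28:1,fatty acid,FA 28:1,,
FA 28:2,fatty acid,FA 28:2,,
FA 28:4,fatty acid,FA 28:4,,
FA 28:5,fatty acid,FA 28:5,,
FA 28:6,fatty acid,FA 28:6,,
FA 29:0,fatty acid,FA 29:0,,
FA 30:0,fatty acid,FA 30:0,,
FA 30:1,fatty acid,FA 30:1,,
FA 30:2,fatty acid,FA 30:2,,
FA 30:4,fatty acid,FA 30:4,,
FA 30:5,fatty acid,FA 30:5,,
FA 30:6,fatty acid,FA 30:6,,
FA 31:0,fatty acid,FA 31:0,,
FA 32:0,fatty acid,FA 32:0,,
FA 32:4,fatty acid,FA 32:4,,
FA 32:5,fatty acid,FA 32:5,,
FA 32:6,fatty acid,FA 32:6,,
FA 33:0,fatty acid,FA 33:0,,
FA 34:0,fatty acid,FA 34:0,,
FA 34:4,fatty acid,FA 34:4,,
FA 34:5,fatty acid,FA 34:5,,
FA 34:6,fatty acid,FA 34:6,,
pyruvic acid,polar carboxylic acid,,88.06,d3-pyruvic acid
lactic acid,polar carboxylic acid,,90.08,d3-lactic acid
succinic acid,polar carboxylic acid,,118.09,"2,2,3,3-d4-succinic acid"
methylmalonic acid,polar carboxylic acid,,118.09,"2,2,3,3-d4-succinic acid"
fumaric acid,polar carboxylic acid,,116.07,d4-fumaric acid
malic acid,polar carboxylic acid,,134.09,"2,3,3-d3-malic acid"
oxaloacetic acid,polar carboxylic acid,,132.07,"2,3,3-d3-malic acid"
2-hydroxyglutaric acid,polar carboxylic acid,,148.11,"2,3,3-d3-malic acid"
citric acid,polar carboxylic acid,,192.12,"2,2,4,4-d4-citric acid"
isocitric acid,polar carboxylic acid,,192.12,"2,2,4,4-d4-citric acid"
cis-aconitic acid,polar carboxylic acid,,174.11,"2,2,4,4-d4-citric acid"
alpha-ketoglutaric acid,polar carboxylic acid,,146.1,d3-pyruvic acid
glycolic acid,polar carboxylic acid,,76.05,d3-lactic acid
oxalic acid,polar carboxylic acid,,90.03,d3-lactic acid
3-hydroxybutyric acid,polar carboxylic acid,,104.1,d3-lactic acid
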