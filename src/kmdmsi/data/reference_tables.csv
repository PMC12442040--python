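table,cloud,series,mz_exp,intensity,best_match,composition_printed,ion_composition,adduct,mz_theoretical_printed,delta_ppm_printed,note
1,1,,851.7103,5030000000.0,TG 50:3,C53 H96 O6 Na,C53 H96 O6 Na,[M+Na]+,851.7099,0.5,
1,1,,853.7261,6230000000.0,TG 50:2,C53 H98 O6 Na,C53 H98 O6 Na,[M+Na]+,853.7256,0.6,
1,1,,867.6846,5370000000.0,DG 53:9,C56 H92 O5 Na,C56 H92 O5 Na,[M+Na]+,867.6837,1.0,
1,1,,869.7,7870000000.0,DG 53:8,C56 H94 O5 Na,C56 H94 O5 Na,[M+Na]+,869.6993,0.8,
1,1,,871.7158,2600000000.0,TG 50:1,C53 H100 O6 K,C53 H100 O6 K,[M+K]+,871.7151,0.8,
1,1,,879.7418,8730000000.0,TG 52:3,C55 H100 O6 Na,C55 H100 O6 Na,[M+Na]+,879.7412,0.7,
1,1,,881.7584,7840000000.0,TG 52:2,C55 H102 O6 Na,C55 H102 O6 Na,[M+Na]+,881.7569,1.7,
1,1,,893.6999,2570000000.0,TG 52:4,C55 H98 O6 K,C55 H98 O6 K,[M+K]+,893.6995,0.4,
1,1,,895.7166,7620000000.0,TG 52:3,C55 H100 O6 K,C55 H100 O6 K,[M+K]+,895.7152,1.6,rounding-boundary
1,1,,897.7317,6340000000.0,TG 52:2,C55 H102 O6 K,C55 H102 O6 K,[M+K]+,897.7308,1.0,
1,1,,907.7737,2610000000.0,TG 54:3,C57 H104 O6 Na,C57 H104 O6 Na,[M+Na]+,907.7725,1.3,
1,2,,549.4883,3000000000.0,MG 30:0 or DG O-30:0,C33 H66 O4 Na,C33 H66 O4 Na,[M+Na]+,549.4853,5.5,
1,2,,551.5038,1520000000.0,MG 32:2 or DG O-32:2,C35 H67 O4,C35 H67 O4,[M+H]+,551.5034,0.7,
1,2,,573.488,2070000000.0,MG 32:2 or DG O-32:2,C35 H66 O4 Na,C35 H66 O4 Na,[M+Na]+,573.4853,4.7,
1,2,,575.5039,1530000000.0,MG 32:1 or DG O-32:1,C35 H68 O4 Na,C35 H68 O4 Na,[M+Na]+,575.501,5.0,
1,2,,577.5187,28700000000.0,MG 32:0 or DG O-32:0,C35 H70 O4 Na,C35 H70 O4 Na,[M+Na]+,577.5166,3.6,
1,2,,601.5189,7510000000.0,MG 34:2 or DG O-34:2,C37 H70 O4 Na,C37 H70 O4 Na,[M+Na]+,601.5166,3.8,
1,2,,603.5351,15400000000.0,MG 34:1 or DG O-34:1,C37 H72 O4 Na,C37 H72 O4 Na,[M+Na]+,603.5323,4.6,
1,2,,605.551,3530000000.0,MG 34:0 or DG O-34:0,C37 H74 O4 Na,C37 H74 O4 Na,[M+Na]+,605.5479,5.1,
2,3,A1,820.5254,6230000000.0,PC 36:4 or PE 39:4,C44 H80 N O8 P K,C44 H80 N O8 P K,[M+K]+,820.5253,0.1,
2,3,A1,822.5398,35900000000.0,PC 36:3 or PE 39:3,C44 H82 N O8 P K,C44 H82 N O8 P K,[M+K]+,822.541,1.5,
2,3,A1,824.5559,9950000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P K,C44 H84 N O8 P K,[M+K]+,824.5566,0.8,
2,3,A1,826.5722,10100000000.0,PC 36:1 or PE 39:1,C44 H86 N O8 P K,C44 H86 N O8 P K,[M+K]+,826.5723,0.1,
2,3,A2,796.5251,50100000000.0,PC 34:2 or PE 37:2,C42 H80 N O8 P K,C42 H80 N O8 P K,[M+K]+,796.5253,0.3,
2,3,A2,798.5416,77300000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P K,C42 H82 N O8 P K,[M+K]+,798.541,0.8,
2,3,A2,806.5667,15300000000.0,PC 36:3 or PE 39:3,C44 H82 N O8 P Na,C44 H82 N O8 P Na,[M+Na]+,806.567,0.4,
2,3,A2,808.5825,12200000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P Na,C44 H84 N O8 P Na,[M+Na]+,808.5827,0.2,
2,3,A3,763.4667,11800000000.0,PA 38:4,C41 H73 O8 P K,C41 H73 O8 P K,[M+K]+,763.4675,1.0,
2,3,A3,765.4824,15200000000.0,PA 38:3,C41 H75 O8 P K,C41 H75 O8 P K,[M+K]+,765.4831,0.9,
2,3,A3,770.5099,3450000000.0,PC 32:1 or PE 35:1,C40 H78 N O8 P K,C40 H78 N O8 P K,[M+K]+,770.5097,0.3,
2,3,A3,780.5515,25300000000.0,PC 34:2 or PE 37:2,C42 H80 N O8 P Na,C42 H80 N O8 P Na,[M+Na]+,780.5514,0.1,
2,3,A3,782.5678,38300000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P Na,C42 H82 N O8 P Na,[M+Na]+,782.567,1.0,
2,3,A3,786.6008,4660000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P,C44 H85 N O8 P,[M+H]+,786.6007,0.1,
2,3,A4,737.4516,19800000000.0,PA 36:3,C39 H71 O8 P K,C39 H71 O8 P K,[M+K]+,737.4518,0.3,
2,3,A4,739.4676,32100000000.0,PA 36:2,C39 H73 O8 P K,C39 H73 O8 P K,[M+K]+,739.4675,0.1,
2,3,A4,747.493,9130000000.0,PA 38:4,C41 H73 O8 P Na,C41 H73 O8 P Na,[M+Na]+,747.4935,0.7,
2,3,A4,749.5087,5760000000.0,PA 38:3,C41 H75 O8 P Na,C41 H75 O8 P Na,[M+Na]+,749.5092,0.7,
2,3,A4,758.5695,7660000000.0,PC 34:2 or PE 37:2,C42 H80 N O8 P,C42 H81 N O8 P,[M+H]+,758.5694,0.1,
2,3,A4,760.5842,24500000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P,C42 H83 N O8 P,[M+H]+,760.5851,1.2,
2,3,A5,721.4773,8680000000.0,PA 36:3,C39 H71 O8 P Na,C39 H71 O8 P Na,[M+Na]+,721.4779,0.8,
2,3,A5,723.4932,19800000000.0,PA 36:2,C39 H73 O8 P Na,C39 H73 O8 P Na,[M+Na]+,723.4935,0.4,
2,3,A5,724.4974,1420000000.0,PA 36:2 first isotope,12C38 13C H73 O8 P Na,12C38 13C H73 O8 P Na,[M+Na]+,724.497,0.6,first-isotope
2,3,A6,666.4834,328000000.0,?,,,,,,unidentified
2,3,A6,682.4575,146000000.0,?,,,,,,unidentified
2,3,A6,692.4991,540000000.0,?,,,,,,unidentified
2,3,B1,763.4667,11800000000.0,PA 38:4,C41 H73 O8 P K,C41 H73 O8 P K,[M+K]+,763.4675,1.0,
2,3,B1,794.5095,7040000000.0,PC 34:3 or PE 37:3,C42 H78 N O8 P K,C42 H78 N O8 P K,[M+K]+,794.5097,0.3,
2,3,B1,822.5398,35900000000.0,PC 36:3 or PE 39:3,C44 H82 N O8 P K,C44 H82 N O8 P K,[M+K]+,822.541,1.5,
2,3,B2,739.4676,37300000000.0,PA 36:2,C39 H73 O8 P K,C39 H73 O8 P K,[M+K]+,739.4675,0.1,
2,3,B2,740.4702,10600000000.0,PA 36:2 first isotope,12C38 13C H73 O8 P K,12C38 13C H73 O8 P K,[M+K]+,740.4709,0.9,first-isotope
2,3,B2,767.4999,3020000000.0,PA 38:2,C41 H77 O8 P K,C41 H77 O8 P K,[M+K]+,767.4988,1.4,
2,3,B2,770.5099,3450000000.0,PC 32:1 or PE 35:1,C40 H78 N O8 P K,C40 H78 N O8 P K,[M+K]+,770.5097,0.3,
2,3,B2,798.5405,77300000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P K,C42 H82 N O8 P K,[M+K]+,798.541,0.6,
2,3,B2,804.5505,77300000000.0,PC 36:4 or PE 39:4,C44 H80 N O8 P Na,C44 H80 N O8 P Na,[M+Na]+,804.5514,1.1,
2,3,B3,747.493,9130000000.0,PA 38:4,C41 H73 O8 P Na,C41 H73 O8 P Na,[M+Na]+,747.4935,0.7,
2,3,B3,749.5087,5750000000.0,PA 38:3,C41 H75 O8 P Na,C41 H75 O8 P Na,[M+Na]+,749.5092,0.7,
2,3,B3,778.5357,17600000000.0,PC 34:3 or PE 37:3,C42 H78 N O8 P Na,C42 H78 N O8 P Na,[M+Na]+,778.5357,0.0,
2,3,B3,806.5668,15300000000.0,PC 36:3 or PE 39:3,C44 H82 N O8 P Na,C44 H82 N O8 P Na,[M+Na]+,806.567,0.2,
2,3,B3,808.5823,8950000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P Na,C44 H84 N O8 P Na,[M+Na]+,808.5827,0.5,
2,3,B4,780.5515,25300000000.0,PC 34:2 or PE 37:2,C42 H82 N O8 P Na,C42 H80 N O8 P Na,[M+Na]+,780.5514,0.1,composition-typo-corrected
2,3,B4,808.5825,12200000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P Na,C44 H84 N O8 P Na,[M+Na]+,808.5827,0.2,
2,3,B5,767.5464,583000000.0,SM 36:2;O2,C41 H81 N2 O6 P K,C41 H81 N2 O6 P K,[M+K]+,767.5464,0.0,
2,3,B5,782.5663,38300000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P Na,C42 H82 N O8 P Na,[M+Na]+,782.567,0.9,
2,3,B5,810.5988,1770000000.0,PC 36:1 or PE 39:1,C44 H86 N O8 P Na,C44 H86 N O8 P Na,[M+Na]+,810.5983,0.6,
2,3,B6,756.5548,177000000.0,PC 34:3 or PE 37:3,C42 H78 N O8 P,C42 H79 N O8 P,[M+H]+,756.5538,1.3,
2,3,B6,784.5856,4240000000.0,PC 36:3 or PE 39:3,C44 H82 N O8 P,C44 H83 N O8 P,[M+H]+,784.5851,0.6,
2,3,B7,692.4991,540000000.0,?,,,,,,unidentified
2,3,B7,758.5696,7660000000.0,PC 34:2 or PE 37:2,C42 H80 N O8 P,C42 H81 N O8 P,[M+H]+,758.5694,0.3,
2,3,B7,786.6008,4470000000.0,PC 36:2 or PE 39:2,C44 H84 N O8 P,C44 H85 N O8 P,[M+H]+,786.6007,0.1,
2,3,B8,760.5842,24500000000.0,PC 34:1 or PE 37:1,C42 H82 N O8 P,C42 H83 N O8 P,[M+H]+,760.5851,1.2,
2,3,B8,774.6004,2330000000.0,PC 35:1 or PE 38:1,C43 H84 N O8 P,C43 H85 N O8 P,[M+H]+,774.6007,0.4,
2,3,B8,788.6159,759000000.0,PC 36:1 or PE 39:1,C44 H86 N O8 P,C44 H87 N O8 P,[M+H]+,788.6164,0.6,
3,4,C1,476.3133,629000000.0,LPC O-14:0,C22 H48 N O6 P Na,C22 H48 N O6 P Na,[M+Na]+,476.3111,4.6,
3,4,C1,478.3289,18100000000.0,LPE O-19:2,C24 H48 N O6 P,C24 H49 N O6 P,[M+H]+,478.3292,0.6,
3,4,C1,500.3135,61900000.0,LPE O-19:2,C26 H52 N O6 P,C24 H48 N O6 P Na,[M+Na]+,500.3111,4.8,name-composition-inconsistent-corrected
3,4,C1,502.3289,29300000000.0,LPC O-16:1,C24 H50 N O6 P Na,C24 H50 N O6 P Na,[M+Na]+,502.3268,4.2,
3,4,C1,504.3444,86000000000.0,LPC O-16:0,C24 H52 N O6 P Na,C24 H52 N O6 P Na,[M+Na]+,504.3424,4.0,
3,4,C1,506.3604,4110000000.0,LPC O-18:2 or LPE O-21:2,C26 H52 N O6 P,C26 H53 N O6 P,[M+H]+,506.3605,0.2,
3,4,C2,441.2978,540000000.0,ST 26:2;O4,C26 H42 O4 Na,C26 H42 O4 Na,[M+Na]+,441.2975,0.7,
3,4,C2,469.3293,768000000.0,ST 28:2;O4,C28 H46 O4 Na,C28 H46 O4 Na,[M+Na]+,469.3288,1.1,
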