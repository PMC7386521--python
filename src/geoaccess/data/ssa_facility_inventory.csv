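region_group,country,population_millions,population_60plus_millions,mfl_primary,mfl_hospital,mfl_total,osm_primary,osm_hospital,osm_total,mfl_primary_per_100k,mfl_hospital_per_100k,mfl_total_per_100k,osm_primary_per_100k,osm_hospital_per_100k,osm_total_per_100k
Central Africa,Burundi,13.097,0.534,619,49,668,22,1317,1339,4.726,0.374,5.101,0.168,10.056,10.224
Central Africa,Cameroon,26.265,1.673,2825,181,3006,478,541,1019,10.756,0.689,11.445,1.820,2.060,3.880
Central Africa,Central African Republic,5.360,0.143,526,20,546,17,590,607,9.814,0.373,10.187,0.317,11.008,11.326
Central Africa,Chad,16.435,0.747,1164,79,1243,90,140,230,7.082,0.481,7.563,0.548,0.852,1.399
Central Africa,DRC,89.636,3.908,14096,432,14528,1383,724,2107,15.726,0.482,16.208,1.543,0.808,2.351
Central Africa,Equatorial Guinea,0.925,0.044,28,14,42,2,5,7,3.027,1.514,4.541,0.216,0.541,0.757
Central Africa,Gabon,1.829,0.124,513,17,530,153,56,209,28.053,0.930,28.983,8.367,3.062,11.429
Central Africa,Republic of the Congo,5.244,0.176,308,27,335,81,87,168,5.873,0.515,6.388,1.545,1.659,3.204
East Africa,Djibouti,0.671,0.023,50,13,63,6,26,32,7.449,1.937,9.386,0.894,3.873,4.767
East Africa,Eritrea,5.955,0.259,252,20,272,2,19,21,4.232,0.336,4.568,0.034,0.319,0.353
East Africa,Ethiopia,111.731,4.780,5014,164,5178,184,272,456,4.488,0.147,4.634,0.165,0.243,0.408
East Africa,Kenya,51.513,2.202,5608,394,6002,279,811,1090,10.887,0.765,11.651,0.542,1.574,2.116
East Africa,Rwanda,13.299,0.512,538,48,586,55,82,137,4.046,0.361,4.406,0.414,0.617,1.030
East Africa,Somalia,12.459,0.574,760,73,833,7,40,47,6.100,0.586,6.686,0.056,0.321,0.377
East Africa,South Sudan,14.112,0.545,1684,41,1725,36,68,104,11.933,0.291,12.224,0.255,0.482,0.737
East Africa,Sudan,45.292,2.374,5,259,264,88,300,388,0.011,0.572,0.583,0.194,0.662,0.857
East Africa,Tanzania,61.897,2.762,6159,222,6381,1015,977,1992,9.950,0.359,10.309,1.640,1.578,3.218
East Africa,Uganda,45.982,2.043,3582,121,3703,1728,546,2274,7.790,0.263,8.053,3.758,1.187,4.945
Southern Africa,Angola,29.150,1.043,1289,150,1439,76,162,238,4.422,0.515,4.936,0.261,0.556,0.816
Southern Africa,Botswana,2.443,0.130,560,28,588,80,77,157,22.924,1.146,24.071,3.275,3.152,6.427
Southern Africa,eSwatini,1.362,0.060,124,6,130,6,25,31,9.107,0.441,9.548,0.441,1.836,2.277
Southern Africa,Lesotho,2.232,0.187,92,14,106,20,44,64,4.121,0.627,4.748,0.896,1.971,2.867
Southern Africa,Madagascar,27.555,0.969,2497,117,2614,59,218,277,9.062,0.425,9.486,0.214,0.791,1.005
Southern Africa,Malawi,20.052,0.843,574,83,657,36,194,230,2.863,0.414,3.276,0.180,0.967,1.147
Southern Africa,Mozambique,31.732,1.452,1499,61,1560,740,148,888,4.724,0.192,4.916,2.332,0.466,2.798
Southern Africa,Namibia,2.734,0.164,322,37,359,48,83,131,11.780,1.354,13.133,1.756,3.036,4.792
Southern Africa,South Africa,56.423,4.614,3951,329,4280,252,644,896,7.002,0.583,7.586,0.447,1.141,1.588
Southern Africa,Zambia,18.784,0.713,1163,89,1252,61,129,190,6.192,0.474,6.665,0.325,0.687,1.012
Southern Africa,Zimbabwe,17.363,0.927,1031,170,1201,98,148,246,5.938,0.979,6.917,0.564,0.852,1.417
West Africa,Benin,12.418,0.717,771,48,819,227,214,441,6.209,0.387,6.595,1.828,1.723,3.551
West Africa,Burkina Faso,20.829,1.061,1711,14,1725,292,175,467,8.214,0.067,8.282,1.402,0.840,2.242
West Africa,Ghana,30.256,1.582,1679,178,1857,256,333,589,5.549,0.588,6.138,0.846,1.101,1.947
West Africa,Guinea,14.260,1.024,1482,36,1518,240,97,337,10.393,0.252,10.645,1.683,0.680,2.363
West Africa,Guinea-Bissau,2.027,0.098,0,8,8,11,18,29,0.000,0.395,0.395,0.543,0.888,1.431
West Africa,Ivory Coast,25.170,0.911,1638,95,1733,793,260,1053,6.508,0.377,6.885,3.151,1.033,4.184
West Africa,Liberia,4.953,0.243,668,33,701,126,51,177,13.488,0.666,14.154,2.544,1.030,3.574
West Africa,Mali,20.542,1.154,1446,18,1464,678,140,818,7.039,0.088,7.127,3.301,0.682,3.982
West Africa,Mauritania,4.509,0.282,626,19,645,30,70,100,13.883,0.421,14.304,0.665,1.552,2.218
West Africa,Niger,24.140,1.280,2794,41,2835,154,113,267,11.574,0.170,11.744,0.638,0.468,1.106
West Africa,Nigeria,205.773,10.227,18714,887,19601,557,2888,3445,9.094,0.431,9.526,0.271,1.403,1.674
West Africa,Senegal,17.384,0.943,1198,27,1225,306,184,490,6.891,0.155,7.047,1.760,1.058,2.819
West Africa,Sierra Leone,6.951,0.433,1060,28,1088,148,145,293,15.249,0.403,15.652,2.129,2.086,4.215
West Africa,The Gambia,2.186,0.107,91,5,96,11,58,69,4.162,0.229,4.391,0.503,2.653,3.156
West Africa,Togo,8.296,0.534,149,37,186,92,172,264,1.796,0.446,2.242,1.109,2.073,3.182
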