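id,lat,lon,source
occ0001,9.0712,18.4332,survey
occ0002,37.6686,0.9651,survey
occ0003,,,literature
occ0004,36.9112,2.9006,survey
occ0005,41.4791,22.8792,survey
occ0006,20.6009,9.6026,survey
occ0007,16.3059,11.2475,survey
occ0008,,,literature
occ0009,12.3985,17.4381,survey
occ0010,21.2761,43.8209,survey
occ0011,4.0353,1.1756,survey
occ0012,19.1496,11.5405,survey
occ0013,3.8881,3.7266,survey
occ0014,12.335,2.4543,survey
occ0015,36.0163,45.1961,survey
occ0016,7.4023,13.6837,survey
occ0017,7.9002,38.6776,survey
occ0018,16.2443,37.2211,survey
occ0019,16.7506,47.1751,survey
occ0020,0.5627,5.4917,survey
occ0021,47.0234,14.7338,survey
occ0022,0.128,25.9174,survey
occ0023,21.1097,5.9224,survey
occ0024,3.801,3.2674,survey
occ0025,48.2155,16.6211,survey
occ0026,8.3493,2.988,survey
occ0027,,,literature
occ0028,43.9488,45.5376,survey
occ0029,17.4795,41.3528,survey
occ0030,6.9794,30.7639,survey
occ0031,47.7453,12.9267,survey
occ0032,38.7476,27.1256,survey
occ0033,,,literature
occ0034,8.0835,36.1182,survey
occ0035,,,literature
occ0036,,,literature
occ0037,35.9304,22.1584,survey
occ0038,45.9594,11.3097,survey
occ0039,2.0332,41.4684,survey
occ0040,19.7742,1.5702,survey
occ0041,,,literature
occ0042,40.9185,1.6676,survey
occ0043,29.989,40.5524,survey
occ0044,31.9795,49.3288,survey
occ0045,37.2055,26.7496,survey
occ0046,,,literature
occ0047,16.9743,21.1542,survey
occ0048,3.5712,31.575,survey
occ0049,,,literature
occ0050,43.2904,7.7238,survey
occ0051,35.5342,7.5079,survey
occ0052,4.6891,33.2074,survey
occ0053,45.7788,35.3049,survey
occ0054,15.8665,7.5952,survey
occ0055,,,literature
occ0056,,,literature
occ0057,,,literature
occ0058,31.6936,7.9975,survey
occ0059,15.3844,37.0261,survey
occ0060,27.2784,12.4839,survey
occ0061,8.7415,12.5877,survey
occ0062,47.4703,36.5123,survey
occ0063,40.9214,18.7036,survey
occ0064,20.1676,42.5116,survey
occ0065,12.2605,48.5072,survey
occ0066,19.1315,6.942,survey
occ0067,41.6184,47.5072,survey
occ0068,,,literature
occ0069,8.0845,27.5936,survey
occ0070,47.5934,22.8308,survey
occ0071,,,literature
occ0072,24.301,13.6759,survey
occ0073,45.859,0.06,survey
occ0074,30.558,21.6003,survey
occ0075,11.8502,24.2729,survey
occ0076,1.0633,12.43,survey
occ0077,30.177,48.7655,survey
occ0078,36.0998,39.4963,survey
occ0079,,,literature
occ0080,11.117,46.0831,survey
occ0081,4.9789,49.5692,survey
occ0082,36.9275,17.7483,survey
occ0083,36.155,11.979,survey
occ0084,7.7045,38.7645,survey
occ0085,24.5169,14.5097,survey
occ0086,28.3173,44.6789,survey
occ0087,33.9299,16.5543,survey
occ0088,48.1406,37.5974,survey
occ0089,45.4698,47.7615,survey
occ0090,6.1837,33.3437,survey
occ0091,,,literature
occ0092,31.5168,5.1983,survey
occ0093,14.5433,22.0319,survey
occ0094,39.8712,10.5378,survey
occ0095,21.8471,28.7385,survey
occ0096,16.6628,28.1638,survey
occ0097,10.4173,10.5559,survey
occ0098,3.2223,6.5333,survey
occ0099,16.8243,16.3835,survey
occ0100,17.5094,34.2118,survey
occ0101,32.2914,18.6238,survey
occ0102,0.7241,40.6322,survey
occ0103,35.3659,12.2666,survey
occ0104,39.6036,27.0182,survey
occ0105,17.2817,37.7223,survey
occ0106,12.6991,49.0193,survey
occ0107,48.6031,41.5194,survey
occ0108,,,literature
occ0109,32.5613,32.9436,survey
occ0110,49.2934,37.5507,survey
occ0111,40.7952,21.4287,survey
occ0112,17.3312,9.2528,survey
occ0113,40.0298,7.8751,survey
occ0114,22.89,20.2408,survey
occ0115,24.8156,32.9831,survey
occ0116,6.1405,14.6544,survey
occ0117,,,literature
occ0118,7.2459,10.7364,survey
occ0119,6.2894,20.903,survey
occ0120,29.8894,48.2876,survey
occ0121,26.4517,34.7654,survey
occ0122,29.0518,21.0121,survey
occ0123,30.1651,18.2355,survey
occ0124,20.2623,24.4012,survey
occ0125,30.5261,17.7719,survey
occ0126,32.9075,48.0557,survey
occ0127,29.9292,9.2985,survey
occ0128,11.5894,46.2754,survey
occ0129,7.9857,19.871,survey
occ0130,47.4903,16.6673,survey
occ0131,0.8288,25.7102,survey
occ0132,9.7117,27.0753,survey
occ0133,46.3287,7.5667,survey
occ0134,34.8191,11.7148,survey
occ0135,26.722,25.2473,survey
occ0136,5.5584,22.242,survey
occ0137,40.0758,15.2377,survey
occ0138,39.7954,49.4827,survey
occ0139,42.3924,23.1416,survey
occ0140,0.2273,39.4602,survey
occ0141,6.7484,30.7997,survey
occ0142,44.4027,35.5156,survey
occ0143,,,literature
occ0144,20.3885,45.6604,survey
occ0145,25.3756,14.9109,survey
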