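wavelength_nm,eps_hbo2,eps_hb,mu_melanin,mu_water,mu_fat,mus_reduced
450.000000,1.016325,1.509717,4.016735,0.000400,0.000200,2.752301
455.000000,1.104390,1.577487,3.885765,0.000400,0.000200,2.713048
460.000000,1.182293,1.629135,3.760428,0.000400,0.000200,2.674774
465.000000,1.246788,1.663129,3.640423,0.000400,0.000200,2.637445
470.000000,1.295068,1.678763,3.525471,0.000400,0.000200,2.601028
475.000000,1.324964,1.676409,3.415308,0.000400,0.000200,2.565491
480.000000,1.335125,1.657860,3.309688,0.000400,0.000200,2.530805
485.000000,1.325201,1.626790,3.208378,0.000400,0.000200,2.496939
490.000000,1.296197,1.589339,3.111161,0.000400,0.000200,2.463867
495.000000,1.251517,1.554736,3.017833,0.000400,0.000200,2.431563
500.000000,1.199731,1.535722,2.928200,0.000400,0.000200,2.400000
505.000000,1.160275,1.548398,2.842082,0.000400,0.000200,2.369155
510.000000,1.171184,1.611007,2.759308,0.000400,0.000200,2.339004
515.000000,1.291998,1.741221,2.679718,0.000400,0.000200,2.309526
520.000000,1.588081,1.951899,2.603159,0.000400,0.000200,2.280699
525.000000,2.086675,2.245872,2.529489,0.000400,0.000200,2.252502
530.000000,2.720837,2.611116,2.458573,0.000400,0.000200,2.224916
535.000000,3.311044,3.018182,2.390283,0.000400,0.000200,2.197922
540.000000,3.631786,3.421635,2.324500,0.000400,0.000200,2.171503
545.000000,3.548075,3.766358,2.261108,0.000400,0.000200,2.145640
550.000000,3.131992,3.997886,2.200000,0.000400,0.000200,2.120317
555.000000,2.660944,4.074300,2.141075,0.000400,0.000200,2.095518
560.000000,2.468798,3.976150,2.084235,0.000400,0.000200,2.071228
565.000000,2.716190,3.711219,2.029389,0.000400,0.000200,2.047431
570.000000,3.230954,3.312528,1.976452,0.000400,0.000200,2.024114
575.000000,3.585599,2.830287,1.925339,0.000400,0.000200,2.001262
580.000000,3.414059,2.320463,1.875974,0.000400,0.000200,1.978864
585.000000,2.701439,1.833529,1.828282,0.000400,0.000200,1.956904
590.000000,1.761127,1.406405,1.782193,0.000400,0.000200,1.935373
595.000000,0.949973,1.059105,1.737640,0.000400,0.000200,1.914257
600.000000,0.433934,0.795865,1.694560,0.000400,0.000200,1.893545
605.000000,0.180629,0.609240,1.652893,0.000400,0.000200,1.873226
610.000000,0.082243,0.485268,1.612580,0.000400,0.000200,1.853290
615.000000,0.051271,0.408085,1.573568,0.000400,0.000200,1.833727
620.000000,0.043033,0.363124,1.535804,0.000400,0.000200,1.814525
625.000000,0.041027,0.338731,1.499238,0.000400,0.000200,1.795677
630.000000,0.040574,0.326529,1.463825,0.000400,0.000200,1.777172
635.000000,0.040588,0.321017,1.429518,0.000400,0.000201,1.759002
640.000000,0.040829,0.318872,1.396275,0.000400,0.000201,1.741158
645.000000,0.041221,0.318243,1.364054,0.000400,0.000202,1.723632
650.000000,0.041728,0.318186,1.332817,0.000400,0.000204,1.706416
655.000000,0.042328,0.318278,1.302527,0.000400,0.000207,1.689501
660.000000,0.043008,0.318374,1.273148,0.000400,0.000212,1.672881
665.000000,0.043760,0.318463,1.244646,0.000400,0.000220,1.656548
670.000000,0.044580,0.318599,1.216988,0.000400,0.000233,1.640495
675.000000,0.045467,0.318860,1.190144,0.000400,0.000254,1.624716
680.000000,0.046421,0.319319,1.164083,0.000400,0.000286,1.609202
685.000000,0.047443,0.320038,1.138778,0.000400,0.000332,1.593949
690.000000,0.048535,0.321052,1.114201,0.000400,0.000397,1.578950
695.000000,0.049698,0.322363,1.090326,0.000400,0.000487,1.564199
700.000000,0.050933,0.323935,1.067128,0.000400,0.000606,1.549690
705.000000,0.052242,0.325689,1.044584,0.000400,0.000759,1.535417
710.000000,0.053627,0.327503,1.022670,0.000400,0.000948,1.521375
715.000000,0.055088,0.329217,1.001365,0.000400,0.001174,1.507559
720.000000,0.056627,0.330634,0.980648,0.000400,0.001433,1.493964
725.000000,0.058242,0.331530,0.960499,0.000400,0.001719,1.480583
730.000000,0.059935,0.331669,0.940897,0.000400,0.002020,1.467414
735.000000,0.061705,0.330812,0.921826,0.000400,0.002320,1.454450
740.000000,0.063551,0.328733,0.903266,0.000400,0.002602,1.441687
745.000000,0.065472,0.325235,0.885201,0.000400,0.002847,1.429121
750.000000,0.067465,0.320163,0.867615,0.000400,0.003038,1.416748
755.000000,0.069529,0.313416,0.850491,0.000400,0.003159,1.404563
760.000000,0.071660,0.304953,0.833816,0.000400,0.003200,1.392562
765.000000,0.073856,0.294804,0.817573,0.000400,0.003159,1.380742
770.000000,0.076111,0.283061,0.801749,0.000401,0.003038,1.369097
775.000000,0.078422,0.269883,0.786331,0.000401,0.002847,1.357626
780.000000,0.080783,0.255483,0.771306,0.000402,0.002602,1.346323
785.000000,0.083189,0.240117,0.756662,0.000403,0.002320,1.335186
790.000000,0.085634,0.224073,0.742385,0.000405,0.002020,1.324211
795.000000,0.088110,0.207654,0.728466,0.000408,0.001719,1.313394
800.000000,0.090610,0.191164,0.714893,0.000412,0.001434,1.302733
805.000000,0.093127,0.174890,0.701654,0.000420,0.001174,1.292223
810.000000,0.095653,0.159098,0.688741,0.000432,0.000949,1.281863
815.000000,0.098179,0.144015,0.676142,0.000450,0.000761,1.271649
820.000000,0.100696,0.129826,0.663849,0.000476,0.000610,1.261578
825.000000,0.103194,0.116671,0.651852,0.000516,0.000496,1.251648
830.000000,0.105665,0.104642,0.640142,0.000574,0.000414,1.241855
835.000000,0.108098,0.093789,0.628711,0.000657,0.000363,1.232196
840.000000,0.110484,0.084119,0.617551,0.000774,0.000343,1.222670
845.000000,0.112813,0.075606,0.606653,0.000937,0.000354,1.213273
850.000000,0.115074,0.068196,0.596011,0.001160,0.000402,1.204003
855.000000,0.117258,0.061815,0.585615,0.001460,0.000497,1.194858
860.000000,0.119355,0.056373,0.575460,0.001858,0.000651,1.185835
865.000000,0.121355,0.051774,0.565539,0.002377,0.000882,1.176932
870.000000,0.123250,0.047918,0.555844,0.003044,0.001210,1.168146
875.000000,0.125029,0.044709,0.546370,0.003885,0.001655,1.159476
880.000000,0.126686,0.042054,0.537109,0.004930,0.002231,1.150919
885.000000,0.128210,0.039869,0.528057,0.006205,0.002949,1.142473
890.000000,0.129596,0.038077,0.519207,0.007735,0.003805,1.134136
895.000000,0.130836,0.036612,0.510554,0.009536,0.004778,1.125906
900.000000,0.131923,0.035416,0.502092,0.011621,0.005833,1.117782
905.000000,0.132853,0.034440,0.493816,0.013987,0.006913,1.109760
910.000000,0.133621,0.033643,0.485721,0.016620,0.007948,1.101840
915.000000,0.134222,0.032993,0.477801,0.019491,0.008863,1.094019
920.000000,0.134653,0.032460,0.470053,0.022555,0.009582,1.086296
925.000000,0.134913,0.032024,0.462472,0.025748,0.010042,1.078668
930.000000,0.135000,0.031666,0.455053,0.028993,0.010200,1.071136
935.000000,0.134913,0.031371,0.447792,0.032199,0.010042,1.063695
940.000000,0.134653,0.031127,0.440684,0.035268,0.009582,1.056346
945.000000,0.134222,0.030927,0.433726,0.038094,0.008863,1.049086
950.000000,0.133621,0.030761,0.426914,0.040577,0.007948,1.041913
955.000000,0.132853,0.030624,0.420243,0.042620,0.006913,1.034827
960.000000,0.131923,0.030510,0.413711,0.044142,0.005833,1.027826
965.000000,0.130836,0.030417,0.407314,0.045082,0.004778,1.020908
970.000000,0.129596,0.030340,0.401047,0.045400,0.003804,1.014072
975.000000,0.128210,0.030276,0.394909,0.045082,0.002949,1.007317
980.000000,0.126686,0.030224,0.388895,0.044142,0.002230,1.000641
985.000000,0.125029,0.030181,0.383003,0.042620,0.001653,0.994043
990.000000,0.123250,0.030146,0.377229,0.040577,0.001207,0.987521
995.000000,0.121355,0.030117,0.371571,0.038094,0.000876,0.981075
1000.000000,0.119355,0.030094,0.366025,0.035268,0.000639,0.974703
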