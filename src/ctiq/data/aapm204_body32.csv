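# Size-conversion factors for the 32 cm body reference phantom, keyed by the
# sum of the anteroposterior and lateral patient dimensions (cm).
# Generated from the published exponential fit f = 3.704369*exp(-0.03671937*d_eff)
# with effective diameter d_eff = (AP+LAT)/2.  Editable configuration.
sum_ap_lat_cm,conversion_factor
16,2.7615
18,2.6619
20,2.5659
22,2.4734
24,2.3842
26,2.2983
28,2.2154
30,2.1355
32,2.0586
34,1.9843
36,1.9128
38,1.8438
40,1.7774
42,1.7133
44,1.6515
46,1.5920
48,1.5346
50,1.4792
52,1.4259
54,1.3745
56,1.3249
58,1.2772
60,1.2311
62,1.1867
64,1.1440
66,1.1027
68,1.0630
70,1.0246
72,0.9877
74,0.9521
76,0.9178
78,0.8847
80,0.8528
82,0.8220
84,0.7924
86,0.7638
88,0.7363
90,0.7097
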