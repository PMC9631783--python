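# Dicentric multiplicity distributions from Co-60 gamma calibration
# irradiations (0-4 Gy, 0.5 Gy/min), scored by semi-automated dicentric
# detection with visual validation of every candidate.
dose,cells,d0,d1,d2,d3
0,20400,20379,21,0,0
0.1,4799,4789,10,0,0
0.25,4528,4500,28,0,0
0.5,4159,4102,56,1,0
0.75,4162,4069,92,1,0
1,4540,4380,158,2,0
2,2239,2009,217,13,0
3,1059,846,185,28,0
4,1054,765,234,50,5
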