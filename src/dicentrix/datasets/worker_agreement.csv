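# Paired 0.1 Gy triage classification of 35 occupationally exposed workers
# by the two scoring methods. Cells: a = both < 0.1 Gy, b = semi-automated
# < 0.1 Gy but manual >= 0.1 Gy, c = semi-automated >= 0.1 Gy but manual
# < 0.1 Gy, d = both >= 0.1 Gy.
a,b,c,d
18,4,1,12
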