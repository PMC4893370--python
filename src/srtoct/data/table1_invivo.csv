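# Clinical in vivo SRT evaluation reference: 16 laser applications in four
# patients, transcribed from the published clinical evaluation table that
# accompanies this classification method.  Columns: applied pulse energy in
# microjoules; FFA leakage assessment by the attending ophthalmologist
# (clinical ground truth); manual M-Scan OCT label; classifier calls at the
# 100% specificity, 95% specificity and 100% sensitivity operating points.
# The FFA cell of row 6 is typographically ambiguous in the source table and
# is transcribed as 1, the only reading consistent with the printed accuracy
# row (87.5 / 81.3 / 93.8 / 81.3 %).
energy_uJ,ffa,oct,c100spec,c95spec,c100sens
120,1,1,1,1,1
120,1,1,1,1,1
60,0,0,0,0,1
80,0,0,0,0,1
80,0,1,1,1,1
80,1,1,1,1,1
80,1,1,1,1,1
80,1,0,0,1,1
80,1,1,0,1,1
120,1,1,1,1,1
60,1,1,1,1,1
80,1,1,1,1,1
100,1,1,1,1,1
100,1,1,1,1,1
100,1,1,1,1,1
100,1,1,1,1,1
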