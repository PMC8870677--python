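study_id,activity_kbq_kg,eqd2_rn_gy
A,50,103.2
A,0,0.0
B,25,34.2
B,50,77.4
B,80,140.7
C,50,154.8
C,0,0.0
D,55,174.0
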