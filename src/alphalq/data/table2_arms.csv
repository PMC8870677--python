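study_id,n_patients,activity_kbq_kg,mbq_per_cycle,n_cycles,f_ebrt_pct,f_ebrt_n,os2y_pct,os2y_n,tox_pct,tox_n,os_extraction
A,33,50,3.5,4,100,33,30,10,0,0,text
A,31,0,0,0,100,31,13,4,0,0,text
B,41,25,1.75,3,29,12,37,15,0,0,text
B,39,50,3.5,3,44,17,44,17,18,7,text
B,42,80,5.6,3,36,15,48,20,21,9,text
C,614,50,3.5,6,16,98,30,184,5,31,kaplan_meier
C,307,0,0,0,16,49,18,55,1,3,kaplan_meier
D,49,55,4.125,6,29,14,49,24,NA,NA,kaplan_meier
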