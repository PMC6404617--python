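variant,als_associated,timepoint_hr,n_counted,n_inclusions,expected_consequence
WT,0,24,656,5,N/A
WT,0,48,742,6,N/A
G93A,1,24,333,78,Steric clash
G93A,1,48,503,243,Steric clash
E40D,0,24,187,64,"Loss of van der Waals, Steric clash"
E40D,0,48,267,61,"Loss of van der Waals, Steric clash"
E40G,1,24,267,78,Loss of van der Waals
E40G,1,48,238,186,Loss of van der Waals
E40Q,0,24,217,0,None
E40Q,0,48,229,0,None
E40V,0,24,116,28,Steric clash
E40V,0,48,147,37,Steric clash
E133D,0,24,219,0,None
E133D,0,48,197,0,None
E133G,0,24,221,0,None
E133G,0,48,288,0,None
E133L,0,24,275,0,None
E133L,0,48,373,0,None
E133M,0,24,243,0,None
E133M,0,48,265,0,None
E133V,1,24,324,38,Steric clash
E133V,1,48,254,62,Steric clash
E133del,1,24,192,12,Loss of H-bonds
E133del,1,48,255,60,Loss of H-bonds
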