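sample_id	host_subject_id	host_age	diet	exposure	group
RC-Air.m00.t00	RC-Air.m00	10.0	RC	Air	RC-Air
RC-Air.m00.t01	RC-Air.m00	11.9	RC	Air	RC-Air
RC-Air.m00.t02	RC-Air.m00	13.8	RC	Air	RC-Air
RC-Air.m00.t03	RC-Air.m00	15.7	RC	Air	RC-Air
RC-Air.m00.t04	RC-Air.m00	17.6	RC	Air	RC-Air
RC-Air.m00.t05	RC-Air.m00	19.5	RC	Air	RC-Air
RC-Air.m01.t00	RC-Air.m01	10.0	RC	Air	RC-Air
RC-Air.m01.t01	RC-Air.m01	11.9	RC	Air	RC-Air
RC-Air.m01.t02	RC-Air.m01	13.8	RC	Air	RC-Air
RC-Air.m01.t03	RC-Air.m01	15.7	RC	Air	RC-Air
RC-Air.m01.t04	RC-Air.m01	17.6	RC	Air	RC-Air
RC-Air.m01.t05	RC-Air.m01	19.5	RC	Air	RC-Air
RC-Air.m02.t00	RC-Air.m02	10.0	RC	Air	RC-Air
RC-Air.m02.t01	RC-Air.m02	11.9	RC	Air	RC-Air
RC-Air.m02.t02	RC-Air.m02	13.8	RC	Air	RC-Air
RC-Air.m02.t03	RC-Air.m02	15.7	RC	Air	RC-Air
RC-Air.m02.t04	RC-Air.m02	17.6	RC	Air	RC-Air
RC-Air.m02.t05	RC-Air.m02	19.5	RC	Air	RC-Air
HFHC-Air.m00.t00	HFHC-Air.m00	10.0	HFHC	Air	HFHC-Air
HFHC-Air.m00.t01	HFHC-Air.m00	11.9	HFHC	Air	HFHC-Air
HFHC-Air.m00.t02	HFHC-Air.m00	13.8	HFHC	Air	HFHC-Air
HFHC-Air.m00.t03	HFHC-Air.m00	15.7	HFHC	Air	HFHC-Air
HFHC-Air.m00.t04	HFHC-Air.m00	17.6	HFHC	Air	HFHC-Air
HFHC-Air.m00.t05	HFHC-Air.m00	19.5	HFHC	Air	HFHC-Air
HFHC-Air.m01.t00	HFHC-Air.m01	10.0	HFHC	Air	HFHC-Air
HFHC-Air.m01.t01	HFHC-Air.m01	11.9	HFHC	Air	HFHC-Air
HFHC-Air.m01.t02	HFHC-Air.m01	13.8	HFHC	Air	HFHC-Air
HFHC-Air.m01.t03	HFHC-Air.m01	15.7	HFHC	Air	HFHC-Air
HFHC-Air.m01.t04	HFHC-Air.m01	17.6	HFHC	Air	HFHC-Air
HFHC-Air.m01.t05	HFHC-Air.m01	19.5	HFHC	Air	HFHC-Air
HFHC-Air.m02.t00	HFHC-Air.m02	10.0	HFHC	Air	HFHC-Air
HFHC-Air.m02.t01	HFHC-Air.m02	11.9	HFHC	Air	HFHC-Air
HFHC-Air.m02.t02	HFHC-Air.m02	13.8	HFHC	Air	HFHC-Air
HFHC-Air.m02.t03	HFHC-Air.m02	15.7	HFHC	Air	HFHC-Air
HFHC-Air.m02.t04	HFHC-Air.m02	17.6	HFHC	Air	HFHC-Air
HFHC-Air.m02.t05	HFHC-Air.m02	19.5	HFHC	Air	HFHC-Air
HFHC-IHC.m00.t00	HFHC-IHC.m00	10.0	HFHC	IHC	HFHC-IHC
HFHC-IHC.m00.t01	HFHC-IHC.m00	11.9	HFHC	IHC	HFHC-IHC
HFHC-IHC.m00.t02	HFHC-IHC.m00	13.8	HFHC	IHC	HFHC-IHC
HFHC-IHC.m00.t03	HFHC-IHC.m00	15.7	HFHC	IHC	HFHC-IHC
HFHC-IHC.m00.t04	HFHC-IHC.m00	17.6	HFHC	IHC	HFHC-IHC
HFHC-IHC.m00.t05	HFHC-IHC.m00	19.5	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t00	HFHC-IHC.m01	10.0	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t01	HFHC-IHC.m01	11.9	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t02	HFHC-IHC.m01	13.8	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t03	HFHC-IHC.m01	15.7	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t04	HFHC-IHC.m01	17.6	HFHC	IHC	HFHC-IHC
HFHC-IHC.m01.t05	HFHC-IHC.m01	19.5	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t00	HFHC-IHC.m02	10.0	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t01	HFHC-IHC.m02	11.9	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t02	HFHC-IHC.m02	13.8	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t03	HFHC-IHC.m02	15.7	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t04	HFHC-IHC.m02	17.6	HFHC	IHC	HFHC-IHC
HFHC-IHC.m02.t05	HFHC-IHC.m02	19.5	HFHC	IHC	HFHC-IHC
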