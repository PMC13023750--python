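name,field_T,T1_ms,T2star_ms,M0_rel
lung,0.6,800.0,2.5,0.2
lung,1.5,1100.0,1.8,0.2
myocardium,0.6,701.0,40.0,0.8
myocardium,1.5,1030.0,30.0,0.8
liver,0.6,339.0,30.0,0.7
liver,1.5,586.0,24.0,0.7
fat,0.6,183.0,50.0,1.0
fat,1.5,260.0,40.0,1.0
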