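aida_class,stratum,detailed_outcome,count
0,TRANSITIONAL,OPERATIVE_VD,1
1,TRANSITIONAL,ICD,1
1,TRANSITIONAL,SPONTANEOUS,1
2,CLASSIC,ICD,2
2,CLASSIC,ICD_AFTER_FAILURE,1
2,CLASSIC,OPERATIVE_VD,1
2,NEAR,ICD,2
2,NEAR,ICD_AFTER_FAILURE,1
2,TRANSITIONAL,ICD,2
2,TRANSITIONAL,ICD_AFTER_FAILURE,1
3,CLASSIC,ICD,12
3,CLASSIC,ICD_AFTER_FAILURE,3
3,CLASSIC,OPERATIVE_VD,1
3,NEAR,ICD,3
3,TRANSITIONAL,ICD,8
3,TRANSITIONAL,ICD_AFTER_FAILURE,3
3,TRANSITIONAL,OPERATIVE_VD,2
4,CLASSIC,ICD,7
4,CLASSIC,ICD_AFTER_FAILURE,2
4,NEAR,ICD,2
4,NEAR,ICD_AFTER_FAILURE,1
4,TRANSITIONAL,ICD,9
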