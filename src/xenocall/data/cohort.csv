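sample_id,age_years,sex,diagnosis,mouse_engrafted,mouse_engraftment_days,single_agent_hts
zccs505,15,M,Ewing sarcoma (relapse),yes,49,yes
zccs250,14,M,anaplastic large cell lymphoma (diagnosis),yes,37,no
zccs51,13,F,neuroblastoma (diagnosis),yes,182,yes
zccs59,12,F,Ewing sarcoma (relapse),yes,67,yes
zccs373,1.8,M,neuroblastoma (relapse),yes,73,yes
zccs262,15,M,sarcoma (relapse),yes,38,yes
zccs43,15,M,osteosarcoma (diagnosis),yes,87,yes
zccs170,1.5,M,rhabdomyosarcoma (relapse),no,,no
zccs15,13,M,gastrointestinal stromal tumor (relapse),no,,no
zccs276,11,M,Ewing sarcoma (relapse),no,,yes
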