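sample_id,sample_source,sample_type,cell_viability_pct,labeled_live_cells_millions,pdx_generated,significant_growth
zccs505,mouse_pdx,tissue,44.6,2.5,yes,yes
zccs250,mouse_pdx,cells,30,1.5,yes,yes
zccs51,mouse_pdx,cells,48,2.4,yes,no
zccs59,mouse_pdx,cells,84,4.2,yes,yes
zccs373,mouse_pdx,cells,10,0.5,yes,no
zccs262,mouse_pdx,tissue,15,0.1,yes,yes
zccs43,mouse_pdx,cells,56.6,3,yes,yes
zccs170,patient_tumor,cells,15.4,0.7,yes,no
zccs15,patient_tumor,cells,32.3,1.3,yes,yes
zccs276,patient_tumor,cells,55.5,3.2,yes,no
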