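sample_id,receptor,condition,pair_id,run_batch
MC1,other,media_control,,
MC2,other,media_control,,
V1,other,vehicle_control,P1,
A1,other,agonist,P1,
V2,other,vehicle_control,P2,
A2,other,agonist,P2,
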