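sample_id,assay_id,card,cq,amp_score,cq_conf
MC1,miR-alpha,A,35.0,1.5,0.95
MC2,miR-alpha,A,Undetermined,0,0
V1,miR-alpha,A,25.0,1.5,0.95
A1,miR-alpha,A,24.0,1.5,0.95
V2,miR-alpha,A,25.2,1.5,0.95
A2,miR-alpha,A,24.1,1.5,0.95
MC1,miR-beta,A,28.0,1.5,0.95
MC2,miR-beta,A,28.4,1.5,0.95
V1,miR-beta,A,Undetermined,0,0
A1,miR-beta,A,Undetermined,0,0
V2,miR-beta,A,Undetermined,0,0
A2,miR-beta,A,Undetermined,0,0
MC1,miR-gamma,B,27.1,1.5,0.95
MC2,miR-gamma,B,26.9,1.5,0.95
V1,miR-gamma,B,26.0,1.5,0.95
A1,miR-gamma,B,26.0,1.5,0.95
V2,miR-gamma,B,26.0,1.5,0.95
A2,miR-gamma,B,26.0,1.5,0.95
MC1,miR-delta,B,Undetermined,0,0
MC2,miR-delta,B,Undetermined,0,0
V1,miR-delta,B,29.0,1.5,0.95
A1,miR-delta,B,29.1,1.5,0.95
V2,miR-delta,B,29.5,1.5,0.95
A2,miR-delta,B,Undetermined,0,0
MC1,miR-epsilon,A,27.0,0.5,0.95
MC2,miR-epsilon,A,Undetermined,0,0
V1,miR-epsilon,A,26.0,1.5,0.95
A1,miR-epsilon,A,25.0,1.5,0.95
V2,miR-epsilon,A,26.2,1.5,0.95
A2,miR-epsilon,A,25.3,1.5,0.95
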