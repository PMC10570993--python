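model_id,nup_name,terminus,copy,z,r,alpha,subcomplex,unit
synthetic,SynNup96,C,1,25.0,53.7,0.0,CR,nm
synthetic,SynNup96,C,2,-25.0,53.7,0.0,NR,nm
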