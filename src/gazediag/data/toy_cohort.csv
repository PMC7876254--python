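participant_id,age_years,group,asd_label
toy1,6.5,TD,0
toy2,11.0,ASD,1
toy3,9.0,second_control,
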