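,ETC,Vascular,Spine,Oncology,Functional,Cranial Trauma
ETC,12,0,1,0,0,0
Vascular,1,9,1,1,0,0
Spine,1,0,13,0,0,0
Oncology,3,0,0,19,0,1
Functional,2,0,0,0,3,0
Cranial Trauma,8,0,0,0,0,4
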