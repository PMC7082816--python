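subject,lv_edp,lv_esp,rv_edp,rv_esp,ef
patient1,20,121,3,23,36
patient2,20,140,8,28,31
patient3,20,100,8,23,15
patient4,20,134,3,20,43
patient5,10,140,8,40,45
volunteer,10,120,8,25,58
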