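subject,segment,lge,sp,wm_bl,wm_fu
patient1,1,0,2,1,0
patient1,2,0,1,1,0
patient1,3,0,0,1,2
patient1,4,3,2,3,2
patient1,5,1,2,4,3
patient1,6,1,2,3,1
patient1,7,0,1,1,0
patient1,8,0,0,1,0
patient1,9,0,0,1,1
patient1,10,3,2,3,3
patient1,11,4,2,4,4
patient1,12,2,2,0,1
patient1,13,0,0,0,0
patient1,14,0,3,0,0
patient1,15,0,3,0,0
patient1,16,0,0,0,1
patient1,17,0,3,0,0
patient2,1,0,0,0,0
patient2,2,0,0,0,0
patient2,3,0,2,1,1
patient2,4,0,3,3,2
patient2,5,3,3,4,2
patient2,6,0,1,1,1
patient2,7,1,2,3,1
patient2,8,0,1,0,0
patient2,9,0,1,0,0
patient2,10,1,2,3,2
patient2,11,3,2,3,1
patient2,12,1,1,1,1
patient2,13,1,3,3,2
patient2,14,0,1,0,0
patient2,15,0,2,3,1
patient2,16,0,0,1,1
patient2,17,0,0,3,2
patient3,1,0,0,3,2
patient3,2,0,0,3,2
patient3,3,0,1,3,2
patient3,4,0,2,4,3
patient3,5,0,2,3,3
patient3,6,0,2,3,2
patient3,7,0,1,3,2
patient3,8,0,0,3,2
patient3,9,0,0,3,2
patient3,10,1,2,4,3
patient3,11,1,2,3,2
patient3,12,0,0,3,2
patient3,13,0,0,3,2
patient3,14,0,0,3,2
patient3,15,0,2,4,2
patient3,16,0,0,3,2
patient3,17,0,0,3,2
patient4,1,0,0,0,0
patient4,2,0,1,0,0
patient4,3,0,0,0,0
patient4,4,0,0,0,0
patient4,5,0,0,0,0
patient4,6,0,0,0,0
patient4,7,1,3,1,1
patient4,8,1,3,0,1
patient4,9,0,0,0,0
patient4,10,0,0,0,0
patient4,11,0,0,0,0
patient4,12,0,0,0,0
patient4,13,2,3,3,2
patient4,14,1,3,3,2
patient4,15,0,2,1,1
patient4,16,0,0,0,0
patient4,17,3,3,4,4
patient5,1,0,0,0,0
patient5,2,0,0,0,0
patient5,3,0,0,0,0
patient5,4,0,1,0,0
patient5,5,4,1,2,2
patient5,6,0,0,0,0
patient5,7,0,2,0,0
patient5,8,0,0,0,0
patient5,9,0,0,0,0
patient5,10,1,0,1,1
patient5,11,4,0,3,3
patient5,12,0,0,1,1
patient5,13,1,1,0,0
patient5,14,0,0,0,0
patient5,15,0,0,1,1
patient5,16,3,0,3,3
patient5,17,0,0,0,0
volunteer,1,0,0,0,0
volunteer,2,0,0,0,0
volunteer,3,0,0,0,0
volunteer,4,0,0,0,0
volunteer,5,0,0,0,0
volunteer,6,0,0,0,0
volunteer,7,0,0,0,0
volunteer,8,0,0,0,0
volunteer,9,0,0,0,0
volunteer,10,0,0,0,0
volunteer,11,0,0,0,0
volunteer,12,0,0,0,0
volunteer,13,0,0,0,0
volunteer,14,0,0,0,0
volunteer,15,0,0,0,0
volunteer,16,0,0,0,0
volunteer,17,0,0,0,0
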