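protein,sugar,dde_el,dde_vdw,dde_nb_printed,p_ddv,dde_tot
MET16,trehalose,-679.18,-1.57,-680.75,0.0011,-6.16
MET16,sucrose,-418.91,8.75,-410.17,0.0009,-39.37
AQ16,trehalose,384.65,-31.36,353.29,0.0034,-37.93
AQ16,sucrose,1166.77,4.06,1161.83,-0.0015,-49.89
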