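channel,mni_x,mni_y,mni_z,brodmann_area,anatomical_label,overlap
1,51,46.33,16.33,45,Pars triangularis Broca's area,0.60517
1,51,46.33,16.33,46,Dorsolateral PFC,0.39483
2,31.67,65,17,10,Frontopolar area,0.80989
2,31.67,65,17,46,Dorsolateral PFC,0.19011
3,50.33,51.67,-1.33,45,Pars triangularis Broca's area,0.029197
3,50.33,51.67,-1.33,46,Dorsolateral PFC,0.9635
3,50.33,51.67,-1.33,47,Inferior prefrontal gyrus,0.0072993
4,30.67,68.33,-1.67,10,Frontopolar area,0.36093
4,30.67,68.33,-1.67,11,Orbitofrontal area,0.63907
5,-25.67,66.67,17.67,10,Frontopolar area,0.86716
5,-25.67,66.67,17.67,46,Dorsolateral PFC,0.13284
6,-46,49.33,17.33,45,Pars triangularis Broca's area,0.41985
6,-46,49.33,17.33,46,Dorsolateral PFC,0.58015
7,-27.67,67.33,0.67,10,Frontopolar area,0.51495
7,-27.67,67.33,0.67,11,Orbitofrontal area,0.48505
8,-47.67,51.67,-0.67,10,Frontopolar area,0.022642
8,-47.67,51.67,-0.67,45,Pars triangularis Broca's area,0.037736
8,-47.67,51.67,-0.67,46,Dorsolateral PFC,0.93962
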