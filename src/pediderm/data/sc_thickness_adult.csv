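mean_um,sd_um,site,reference
13.2,2.3,Abdomen,Khiao In et al. 2019
21,2.3,Forearm,Choe et al. 2018
19,1.3,Forearm,Choe et al. 2018
10.4,3.2,Forearm,Sauermann et al. 2002
11.2,1.9,Forearm,Sauermann et al. 2002
13.3,,Buttock,Therkildsen et al. 1998
18.3,4.9,Dorsal forearm,Sandby-Moller et al. 2003
11,2.2,Shoulder,Sandby-Moller et al. 2003
14.9,3.4,Buttock,Sandby-Moller et al. 2003
9.3,,Back of hand,Robertson and Rees 2010
8.7,,Centre of calf,Robertson and Rees 2010
10.9,,Outer forearm,Robertson and Rees 2010
6.2,,Inner forearm,Robertson and Rees 2010
6.4,,Inner upper arm,Robertson and Rees 2010
8.4,,Upper back,Robertson and Rees 2010
6.5,,Chest,Robertson and Rees 2010
6.3,,Abdomen,Robertson and Rees 2010
5.8,,Corner of eye,Robertson and Rees 2010
6.3,,Temple,Robertson and Rees 2010
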