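dataset,n_latent_variables,Rc2,Rp2,RMSEC,RMSEP,MRE
1,3,0.741,0.593,0.763,0.861,12.5
2,3,0.670,0.767,0.821,0.757,12.8
3,3,0.680,0.751,0.824,0.742,9.7
4,3,0.726,0.615,0.788,0.819,11.0
5,3,0.677,0.600,0.826,0.942,14.3
6,3,0.670,0.683,0.853,0.786,10.4
7,3,0.735,0.642,0.766,0.826,12.8
8,3,0.693,0.539,0.806,1.012,14.6
9,3,0.709,0.734,0.791,0.754,12.9
10,3,0.682,0.760,0.824,0.720,10.5
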