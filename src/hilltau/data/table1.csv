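sample,Orox PK,Naugard P,Anox 20,tau_obs,tau_sd,n_rep,tau_fitted_ref
biodiesel,0,0,0,5.66,0.43,3,5.66
anox20-0.083,0,0,0.083,8.39,0.12,3,8.01
anox20-0.125,0,0,0.125,9.45,0.16,3,9.20
anox20-0.167,0,0,0.167,10.99,0.04,3,10.39
anox20-0.250,0,0,0.250,12.42,0.38,3,12.74
naugardp-0.083,0,0.083,0,6.12,0.25,3,5.74
naugardp-0.125,0,0.125,0,5.95,0.19,3,5.77
naugardp-0.167,0,0.167,0,5.57,0.01,3,5.81
naugardp-0.250,0,0.250,0,5.82,0.50,3,5.88
oroxpk-0.083,0.083,0,0,6.60,0.06,3,6.03
oroxpk-0.125,0.125,0,0,6.96,0.12,3,6.22
oroxpk-0.167,0.167,0,0,7.00,0.03,3,6.41
oroxpk-0.250,0.250,0,0,5.82,0.05,3,6.78
naugardp0.167-anox0.083,0,0.167,0.083,7.75,0.48,3,8.16
naugardp0.125-anox0.125,0,0.125,0.125,9.30,0.93,3,9.31
naugardp0.083-anox0.167,0,0.083,0.167,10.86,0.00,3,10.45
oroxpk0.167-naugardp0.083,0.167,0.083,0,5.59,0.00,3,6.48
oroxpk0.125-naugardp0.125,0.125,0.125,0,5.75,0.01,3,6.33
oroxpk0.083-naugardp0.167,0.083,0.167,0,6.14,0.34,3,6.18
oroxpk0.167-anox0.083,0.167,0,0.083,10.46,0.28,3,11.41
oroxpk0.125-anox0.125,0.125,0,0.125,12.25,0.46,3,12.56
oroxpk0.083-anox0.167,0.083,0,0.167,13.11,0.29,3,13.40
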