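strain,parameter,H_uM,value,lower,upper,unit
1335,b_max,,0.51,0.48,0.54,per_h
1335,K,,2.1,1.7,2.4,uM
1335,n,,3.2,2.5,3.9,dimensionless
1335,death_rate,,0.0024,0.0018,0.0030,per_h
1335,consumption,,5.4,5.1,5.7,fmole_per_cell
1335,release_rate,,0.27,0.25,0.29,fmole_per_cell_per_h
1340,b_max,,0.44,0.43,0.45,per_h
1340,K,,1.3,1.2,1.4,uM
1340,n,,1.5,1.4,1.7,dimensionless
1340,death_rate,,0.015,0.014,0.016,per_h
1340,consumption,,3.1,3.0,3.2,fmole_per_cell
1340,release_rate,0,0.52,0.42,0.62,fmole_per_cell_per_h
1340,release_rate,0.58,0.83,0.70,0.96,fmole_per_cell_per_h
1340,release_rate,0.65,0.78,0.70,0.86,fmole_per_cell_per_h
1340,release_rate,0.73,0.53,0.45,0.61,fmole_per_cell_per_h
1340,release_rate,0.80,0.38,0.32,0.45,fmole_per_cell_per_h
1340,release_rate,1.07,0.08,0.05,0.11,fmole_per_cell_per_h
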