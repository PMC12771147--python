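sample_id,uvvis_mean,uvvis_sd,dia_mean,dia_sd,n
A1,3.20e-3,1.00e-4,3.36e-3,1.52e-4,3
A2,5.16e-3,4.16e-4,4.83e-3,4.93e-4,3
A3,1.33e-3,2.00e-3,1.26e-3,1.52e-4,3
A4,8.00e-4,1.00e-4,7.66e-4,1.52e-4,3
A5,1.46e-3,2.08e-4,1.56e-3,1.00e-4,3
A6,5.00e-4,1.00e-4,5.00e-4,1.00e-4,3
A7,1.30e-3,1.00e-4,1.20e-3,1.00e-4,3
A8,7.00e-4,1.00e-4,7.33e-4,1.52e-4,3
A9,4.46e-3,3.05e-4,4.56e-3,6.02e-4,3
A10,2.50e-3,1.00e-4,2.36e-3,2.08e-4,3
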