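method,intercept,slope,r_squared
LSdNDF,25.543,0.4183,0.41
IVdNDF_075,-22.009,1.0362,0.90
IVdNDF,-16.169,1.0576,0.96
ISdNDF,-3.246,0.9254,0.91
RochaJunior,24.606,0.4391,0.42
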