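{
 "c1": 0.35433333333333333,
 "eta_sat": 10.63,
 "eta_inf": 5.5,
 "s2": 41.0,
 "lambda": 9.83,
 "extension_mode": "linear_in_s",
 "n0": 64,
 "kappa_b": 30,
 "f": 20,
 "provenance": "levels eta_sat=10.63, eta_inf=5.5 are the published reference values; breakpoints and decay scale from a 200-run Langevin extraction (N0=64, kappa_b=30, f=20, kBT=1.2, eta=0.7; pore friction 5.48 from a flexible-chain control): buckling onset s1~30, decay onset s2~41, decay scale 9.8 beads; see data/reference_trace_md.csv"
}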