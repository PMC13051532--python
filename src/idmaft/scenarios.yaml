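# Simulation scenario catalogue.
#
# Naming: E = early censoring U(85,95), L = late censoring U(95,105);
# the number is the mean age at death after diagnosis (65 or 80);
# the size suffix is the initial cohort size L(arge)=2400, M=1200, S=500.
# All scenarios share: entry age U(55,60), sex ~ Bernoulli(0.4), visit
# half-widths U(0,3), mean onset age 95, mean disease-free death age 85,
# sex coefficients (0.03, -0.04, -0.08), shapes (7.0, 10.8, 8.1) and
# random-effect variances (0.008237, 0.000714, 0.000063) with
# cov(u_i, u_m1) = 0.000115.

E65_L: {n_initial: 2400, censor_bounds: [85, 95], mean_death_diseased: 65}
E80_L: {n_initial: 2400, censor_bounds: [85, 95], mean_death_diseased: 80}
L65_L: {n_initial: 2400, censor_bounds: [95, 105], mean_death_diseased: 65}
L80_L: {n_initial: 2400, censor_bounds: [95, 105], mean_death_diseased: 80}
E65_M: {n_initial: 1200, censor_bounds: [85, 95], mean_death_diseased: 65}
E80_M: {n_initial: 1200, censor_bounds: [85, 95], mean_death_diseased: 80}
L65_M: {n_initial: 1200, censor_bounds: [95, 105], mean_death_diseased: 65}
L80_M: {n_initial: 1200, censor_bounds: [95, 105], mean_death_diseased: 80}
E65_S: {n_initial: 500, censor_bounds: [85, 95], mean_death_diseased: 65}
E80_S: {n_initial: 500, censor_bounds: [85, 95], mean_death_diseased: 80}
L65_S: {n_initial: 500, censor_bounds: [95, 105], mean_death_diseased: 65}
L80_S: {n_initial: 500, censor_bounds: [95, 105], mean_death_diseased: 80}
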