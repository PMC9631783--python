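# Published linear-quadratic calibration curves Y = C + alpha*D + beta*D^2
# for manual and semi-automated dicentric scoring (standard errors only;
# no coefficient covariance was published).
label,c,se_c,alpha,se_alpha,beta,se_beta,cov_c_alpha,cov_c_beta,cov_alpha_beta
manual,0.00105,0.00010,0.0355,0.0041,0.0644,0.0027,,,
semi_automated,0.00097,0.00021,0.016,0.0022,0.018,0.0012,,,
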