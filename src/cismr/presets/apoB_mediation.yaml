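# Mediation-calibrated chain: total effect log(1.09), exposure->mediator
# effect 0.049 and mediator->outcome effect 0.51, so the true proportion
# mediated is ~29%.
n_snps: 13
true_theta: 0.0
xi_mean: 0.35
xi_sd: 0.05
mediator_chain:
  a: 0.049
  b: 0.51
  theta_direct: 0.061187696241052414
  n_mediator_snps: 20
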