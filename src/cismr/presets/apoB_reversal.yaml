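# Exposure->outcome chain whose univariable (total) effect is log(1.09)
# while the mediator-adjusted direct effect is log(0.84): the ApoB
# sign-reversal configuration.
n_snps: 13
true_theta: 0.0
xi_mean: 0.35
xi_sd: 0.05
mediator_chain:
  a: 0.049
  b: 5.316960885425106
  theta_direct: -0.1743533871447778
  n_mediator_snps: 20
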