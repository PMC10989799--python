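s0,theta,df,tau_end,converged
1.0,0.0,0.08478233261293334,15820.0,True
1.0,0.05,0.085849052472172,15780.0,True
10.0,0.0,0.054412902705359624,20530.0,True
10.0,0.05,0.05720541392079483,19670.0,True
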