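# Baseline simulation parameters (illustrative, daily rates).
# k is one twentieth of q: fewer predatory ants than borers.
# mu is variable in the analysis; 0.03 is the reference (lowest) value.
q = 700.0
k = 35.0
r = 0.01
alpha = 0.01
delta = 0.01
epsilon = 0.2
theta = 0.23
mu = 0.03
phi = 2.0
omega = 0.17
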