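# Default kinetic parameters for the four conductance-based receptor models
# (two-state transmitter-binding scheme; NMDA adds a voltage-dependent
# magnesium block, GABA_B a G-protein second-messenger cascade with Hill-type
# activation).  Values are the classic published constants of the
# Destexhe-family kinetic synapse models; they are defaults, overridable per
# synapse in configuration.
#
# Units: alpha, k1 in mM^-1 ms^-1; beta, k2, k3, k4 in ms^-1; esyn, threshold
# in mV; cmax (transmitter pulse amplitude) in mM; cdur (pulse duration) in
# ms; mg in mM; kd dimensionless (in s^n units of the cascade variable).
AMPA:
  alpha: 1.1
  beta: 0.19
  esyn: 0.0
  cmax: 1.0
  cdur: 1.0
  threshold: 0.0
NMDA:
  alpha: 0.072
  beta: 0.0066
  esyn: 0.0
  cmax: 1.0
  cdur: 1.0
  threshold: 0.0
  mg: 1.0
GABA_A:
  alpha: 5.0
  beta: 0.18
  esyn: -80.0
  cmax: 1.0
  cdur: 1.0
  threshold: 0.0
GABA_B:
  k1: 0.52
  k2: 0.0013
  k3: 0.098
  k4: 0.033
  kd: 100.0
  n: 4
  esyn: -95.0
  cmax: 1.0
  cdur: 1.0
  threshold: 0.0
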