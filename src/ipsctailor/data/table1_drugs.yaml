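# Reference-drug specifications: per-current IC50 (uM), tested bath
# concentrations (uM) and the pacing cycle length (s) matching the mean
# spontaneous rate observed in the optical-mapping experiments for each
# compound. A missing current entry means "no significant effect".
# Paracetamol is the no-effect negative control; its tested concentrations
# are nominal (none are printed for it in the source table).
dofetilide:
  ic50:
    I_Kr: 0.0052
    I_Na: 147.9
    I_CaL: 26.7
    I_Ks: 415.8
  hill_coefficient: 1.0
  concentrations: [0.03, 0.1, 0.3, 1.0]
  cycle_length: 1.375
quinidine:
  ic50:
    I_Kr: 0.3
    I_Na: 16.6
    I_CaL: 15.6
  hill_coefficient: 1.0
  concentrations: [0.01, 0.1, 1.0, 10.0]
  cycle_length: 1.176
sotalol:
  ic50:
    I_Kr: 111.4
    I_Na: 7013.9
    I_CaL: 193.3
  hill_coefficient: 1.0
  concentrations: [0.3, 3.0, 30.0, 300.0]
  cycle_length: 0.933
verapamil:
  ic50:
    I_Kr: 0.25
    I_Na: 32.5
    I_CaL: 0.2
  hill_coefficient: 1.0
  concentrations: [0.01, 0.1, 1.0, 10.0]
  cycle_length: 0.905
paracetamol:
  ic50: {}
  hill_coefficient: 1.0
  concentrations: [1.0, 10.0, 100.0]
  cycle_length: 1.0
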