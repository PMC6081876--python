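# Literature-derived 1-compartment physiology for adult zebrafish.
# Whole-body lipid/water fractions are volume fractions at unit density.
name: zebrafish-adult-1c
species: Danio rerio
life_stage: adult

F_gill: 9.167   # uL/s; countercurrent gill water flow [Pery et al. 2014]
k_m: 1.0e-05    # 1/s; default first-order decomposition rate [entered]
V_t: 500.0      # uL; body volume of a 0.5 g fish at unit density [entered]
L_body: 0.05    # whole-body lipid volume fraction [entered]
W_body: 0.78    # whole-body water volume fraction [entered]
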