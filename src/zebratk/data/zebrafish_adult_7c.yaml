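# Literature-derived 7-compartment physiology for adult zebrafish (Danio rerio).
# Provenance is recorded per entry.  Values marked [entered] are representative
# adult-zebrafish magnitudes entered by the package authors in the spirit of the
# Pery et al. (2014) zebrafish PBTK parameterisation; users with a primary
# parameter table should supply their own config file and cite it here.
name: zebrafish-adult-7c
species: Danio rerio
life_stage: adult

F_gill: 9.167       # uL/s; countercurrent gill water flow [Pery et al. 2014]
k_m: 1.0e-05        # 1/s; default first-order liver decomposition rate [entered]
f_car: 0.667        # uL/s; total (cardiac) blood flow, ~40 uL/min [entered]

flow_fractions:     # fraction of f_car perfusing each tissue; sums to 1
  brain: 0.05       # [entered]
  gonads: 0.10      # [entered]
  rpt: 0.25         # richly perfused tissue [entered]
  ppt: 0.50         # poorly perfused tissue [entered]
  liver: 0.10       # [entered]

m_tot: 0.5          # g; adult zebrafish body mass [entered]

mass_fractions:     # fraction of m_tot per compartment; sums to <= 1
  blood: 0.05       # [entered]
  brain: 0.01       # [entered]
  gonads: 0.08      # [entered]
  rpt: 0.06         # [entered]
  ppt: 0.78         # [entered]
  liver: 0.012      # [entered]

lipid_content:      # volume fraction of tissue that is lipid
  brain: 0.06       # [entered]
  gonads: 0.10      # [entered]
  rpt: 0.03         # [entered]
  ppt: 0.02         # [entered]
  liver: 0.05       # [entered]

water_content:      # volume fraction of tissue that is water
  brain: 0.78       # [entered]
  gonads: 0.70      # [entered]
  rpt: 0.75         # [entered]
  ppt: 0.76         # [entered]
  liver: 0.72       # [entered]

arterial_blood_share: 0.3333333333333333   # arterial fraction of blood volume [entered]
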