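# Reference dataset: methyl-beta-cyclodextrin treatment of sonicated,
# carbonate-stripped TGN/endosomal membrane vesicles from Cos-7 cells.
# Equilibrium buoyant densities from sucrose-gradient refractometry
# (mean +/- SEM, g/mL), cholesterol mass-remaining fraction M from
# Amplex Red assays (the measured reduction was 83.4 +/- 2.75 %).
measurements:
  rho_pre: 1.096
  rho_pre_sem: 0.003
  rho_post: 1.122
  rho_post_sem: 0.0005
  mass_remaining_M: 0.166
  mass_remaining_M_sem: 0.0275
  rho_sensitive: 1.067
# DLS hydrodynamic diameters (nm, mean +/- SD of triplicates) per
# gradient band and condition.
dls:
  - {condition: control, fraction_class: buoyant, diameter_mean_nm: 779.5, diameter_sd_nm: 28.2}
  - {condition: control, fraction_class: dense, diameter_mean_nm: 453.0, diameter_sd_nm: 177.1}
  - {condition: treated, fraction_class: buoyant, diameter_mean_nm: 42.2, diameter_sd_nm: 11.5}
  - {condition: treated, fraction_class: dense, diameter_mean_nm: 270.2, diameter_sd_nm: 68.8}
# Volume decline (%) as reported alongside the study's 40.4% diameter
# decline; arithmetically inconsistent with the diameters (which give
# 78.8%) and carried here so the report can flag the discrepancy.
reported_observed_volume_decline_pct: 88.8
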