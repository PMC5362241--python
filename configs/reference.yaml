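# Reference run configuration: every key at its default value.
# `rhozone run configs/reference.yaml` ignites a centred RhoA pulse on the
# default grid; set mech.pe to choose the regime (depinning near Pe = 11
# for these kinetics).
kinetics:
  alpha: 1.0      # diffusion time / reaction time
  kappa1: 0.2     # half-saturation of NMIIA -> RhoA recruitment
  kappa2: 0.2     # half-saturation of RhoA -> NMIIA recruitment
  n: 4            # Hill coefficient
mech:
  pe: 12.0        # Peclet number (contractile advection / diffusion)
  K: 1.0          # active-stress half-saturation
  advection_mode: both   # or myosin_only
grid:
  length: 40.0    # in hydrodynamic lengths sqrt(eta/gamma)
  n_cells: 400
  bc: noflux_rigid       # or periodic
pulse:
  amplitude: high        # the high fixed point; or a number
  half_width: 1.0
  species: rho           # or both
  shape: tophat          # or gaussian
protocol: null    # e.g. {t_switch: 40.0, pe_after: 0.0, nmiia_decay_factor: 2.0}
t_end: 150.0
record_every: 0.5
seed: 0           # used only by the synthetic-kymograph generator
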