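# Default physiological and environmental inputs of the vineyard scenario.
# Every value can be overridden via the corresponding constructor argument.
architecture:
  k_root: 30.0            # mmol m-2(leaf) s-1 MPa-1
  k_stem_leaf: 12.0
  k_leaf_sym: 25.0
  c_stem: 5.0             # mol m-2 MPa-1 (whole-plant woody storage)
  c_leaf_apo: 0.25
  w_sat_leaf: 8.0         # mol m-2, saturated leaf symplasm water
  v_cav_reservoir: 2.0    # mol m-2 released over 0 -> 100 PLC
  g_bl_leaf: 2000.0       # mmol m-2 s-1
  g_bl_canopy: 1200.0
  wind_speed: 2.0         # m s-1
  absorptance_sw: 0.6
  emissivity: 0.97
soil:
  theta_sat: 0.43
  theta_res: 0.06
  alpha: 300.0            # MPa-1
  n_vg: 2.1
  k_sat_total: 50000.0    # mmol m-2(leaf) s-1 MPa-1, referenced at field capacity
  taw_mm: 180.0
  lai: 1.5
  fractions: [0.3, 0.3, 0.4]
forcing:
  t_day: 25.0             # degC
  rh_day: 60.0            # %
  ppfd_day: 1500.0        # umol m-2 s-1
  t_night: 15.0
  rh_night: 90.0
  ppfd_night: 0.0
  photoperiod_h: 12.0
  co2: 400.0              # ppm
  wind: 2.0
numerics:
  dt: 60.0                # s
  dpsi_max: 0.2           # MPa per substep before subdivision
  failure_plc: 99.5       # % ("100 PLC" operationalised)
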