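# Demonstration configuration for `hgtrade run --config examples/run.yaml`.
#
# The health coefficients below are ILLUSTRATIVE placeholders of literature
# magnitude; they are required configuration and carry no endorsement as
# reference values.  Deflators bring 2008-USD earnings losses and 2005-USD
# VSL to 2020 USD and must come from the user's price data.

seed: 1
mc: true

world:
  n_regions: 10
  n_sectors: 4
  grid_shape: [36, 72]
  trade_share: 0.4
  intensity_gap: 5.0
  coastal_fraction: 0.5

transport:
  local_fraction_peak: 0.6
  local_fraction_min: 0.2
  peak_latitude: 40.0
  advection_cells: 3
  advection_decay: 1.0
  global_mixing: 0.1
  plankton_gain: 0.05
  soil_gain: 0.005
  background_D: 0.5
  background_P: 1.0
  background_S: 50.0

health:
  beta: 0.01      # blood Hg (µg/L) per unit body-weight-adjusted dose
  lambda_: 0.25   # hair Hg (µg/g) per blood Hg (µg/L)
  gamma: 0.18     # IQ points per hair Hg (µg/g)
  phi: 0.066      # FHA log-linear slope per hair Hg (µg/g)
  omega: 0.8      # causality probability
  bw: 70.0
  bw_mode: multiply
  el: 18832.0     # USD(2008) per IQ point
  vsl: 6.3e+6     # USD(2005) per statistical life
  deflators:
    2005: 1.34
    2008: 1.21
  use_country_vsl: true
  vsl_elasticity: 1.0
  vsl_reference_gdp: 40000.0

uncertainty:
  n_iter: 200
  percentiles: [2.5, 97.5]
  components:
    food_intake: [-47.0, 42.0]
    food_concentration: [-37.0, 63.0]
    dose_response: [-59.0, 147.0]
    valuation: [-70.0, 26.0]
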