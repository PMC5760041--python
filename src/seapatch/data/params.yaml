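# Default parameterisation of the Yucatan sea cucumber (patch a) simulation.
# Values are the published survey/market estimates for the 2013 season;
# other_variable_cost and opportunity_cost anchor the reconstructed cost and
# entry-exit sub-models (see docs/methods.md).
population:
  natural_mortality_per_year: 0.58   # yr^-1
  mean_weight_kg: 0.5395             # wet weight per individual
catchability:
  a: 1527.7                          # kg per (ind m^-2) per trip
  b: -15.3                           # kg per trip
fleet:
  initial_effort: 691.0              # trips day^-1
  max_effort: 691.0                  # licensed ceiling, trips day^-1
  phi: 0.10                          # trips per US$ per day; calibrated to
                                     # the observed effort-cessation date
                                     # under the reconstructed sub-models
  opportunity_cost: 85.0             # US$ per trip
  allocation_basis: quasi_profit_then_revenue
  gravity: true                      # effort attraction = income x stock
economics:
  price_intercept: 5486.0            # US$ per tonne gutted
  price_slope: -10.4                 # US$ per tonne per (tonne day^-1)
  price_quantity_basis: wet          # demand slope acts on landed (whole) t
  gas_alpha: 52.5                    # US$ per trip
  gas_beta: 5.2                      # US$ (ind m^-2) per trip
  other_variable_cost: 40.0          # US$ per trip (meals + ice)
  gutted_fraction: 0.6
  annual_discount_rate: 0.10
simulation:
  horizon_days: 240
  season_days: 148                   # survey-to-survey reporting window
  max_trips_per_day: null            # status quo: no daily cap
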