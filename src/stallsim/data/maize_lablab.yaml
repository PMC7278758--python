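# Stall-fed dairy evaluation scenario: multiparous B. indicus x B. taurus
# cows fed maize-lablab stover ad libitum (Ethiopian feeding trial),
# simulated for five monthly steps from calving.
#
# The breed's envelope weights (min_mature_weight, max_attainable_weight)
# and birth weight are not part of the trial data; they are package
# defaults for this crossbred population (see docs/methods.md) and can be
# overridden here.
breed:
  name: "B. indicus x B. taurus dairy cross (Ethiopia)"
  species_class: crossbred
  sex: female
  birth_weight: 30.0
  max_attainable_weight: 535.0
  min_mature_weight: 165.0
  gompertz_mu0: 0.015
  max_daily_gain: 1.2
  peak_milk_yield: 20.0
  peak_month: 2
  lactation_length: 10
  milk_fat: 46.3
  milk_protein: 29.0
  kl: 0.6
animal:
  age: 5.2
  body_weight: 415.0
  lactation_month: 1
  gestation_day: 0
  parity: 3
ration:
  dm: 890.0
  me: 9.4
  ndf: 0.55
  cp: 93.1
  contains_concentrate: false
  offered_dm: ad_libitum
simulation:
  n_steps: 5
  horizontal_distance: 0.0
  vertical_distance: 0.0
  days_per_step: 30.4
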