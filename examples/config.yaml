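# Example configuration for `rainwin run-all --config examples/config.yaml --out out/`
#
# Every section is optional; omitted keys fall back to the defaults the
# package documents. With no `inputs:` section a synthetic study is
# generated first (the `simulate:` keys override SimConfig fields).

seed: 1

simulate:
  n_plots: 30
  years: [2013, 2014, 2015, 2016, 2017, 2018]
  seasonal_mean_mm: 56.0
  seasonal_cv: 1.07
  dropout_rate: 0.12

# minimum study-wide total for a taxon to be retained
min_total: 50

screen:
  threshold: 0.7
  vars: [sand, gravel, cobble, boulder, large_boulder,
         total_cover, herb_cover, grass_cover, n_species, seasonal_rainfall]
  # Reference outcome for the emulated study's covariate set, documented
  # here as configuration (the original screen's correlation table is not
  # recomputable from summaries): sand, boulder, large_boulder, n_species,
  # herb_cover and grass_cover excluded, i.e. retained =
  #   [gravel, cobble, total_cover, seasonal_rainfall]

ordinate:
  vars: [seasonal_rainfall, total_cover, gravel, cobble]
  restarts: 20
  nperm_envfit: 1000
  nperm_permanova: 999
  year_term: true        # year enters the PERMANOVA first (sequential SS)

scan:
  groups: [plants, herbivore, omnivore, predator, detritivore, ant]
  widths: [7, 14, 30]
  offsets: "0:30"

cascade:
  year: numeric          # 'factor' would alias seasonal rainfall
  standardize: true
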