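# Example pipeline configuration (all fields shown with their defaults).
# Run:  invastack run --config examples/config.yaml --out runs/demo

seed: 1                      # master seed; every stage derives its own from it
shape: [100, 100]            # grid rows x cols (>= 20 x 20)
n_species: 30                # virtual species in the pool

# future-scenario forcing (overrides for ScenarioParams; empty = defaults:
# +2.0 C mild / +4.5 C severe, precip x1.05 / x0.90, land-use +0.05 / -0.10)
scenario_params: {}

# virtual-species niches: Gaussian response per layer, optima drawn between
# the given land quantiles, breadths as multiples of the layer sd
niche_layers: [temp_mean, precip_annual]
niche_mu_quantiles: [0.15, 0.85]
niche_sigma_sd_range: [0.35, 0.9]
lam: 500.0                   # expected raw occurrence records per species

n_effort_centres: 3          # sampling-effort bumps (ignored if centres given)
effort_centres: null         # explicit [[row, col], ...] survey centres

# occurrence filtering
n_bins: 6                    # bins per climatic variable in env space
min_records: 30              # minimum records to keep a species

sre_q: 0.025                 # surface-range-envelope quantile for PA design

# Boyce index windows
boyce_window_width: 0.1
boyce_n_windows: 101

retention_threshold: 0.6     # models with CV Boyce <= this are dropped
threshold_mode: crossing     # binarization: crossing | first_crossing
hotspot_fractions: [0.05, 0.10, 0.15]
predictor_sets: [set1, set2]
write_species_rasters: false # per-species binary/suitability TIFFs
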