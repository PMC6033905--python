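# Template configuration for `aodfuse run --config run.yaml`.
# Defaults marked [method] follow the published fusion procedure;
# those marked [choice] are package defaults with no canonical value.

outdir: aodfuse_run
synthetic: true          # generate a seeded scene; set false for file inputs
seed: 1

# fusion stage
r_threshold: 0.5         # [method] correlation gate for gap-filling
min_pairs: 10            # [choice] minimum daily pairs per cell-season fit

# synthetic mode
n_days: 120              # [choice] days cycle through seasons in 90-day blocks
scene_overrides: {}      # any SceneConfig field, e.g. {cloud_miss_prob: 0.3}

# user-data mode (all four required when synthetic: false)
# site_aod_path: site_aod.csv        # columns: date,aod550
# grid_aod_path: grid_aod.csv        # columns: date,row,col,aod,flag
# gridspec_path: gridspec.yaml       # lon/lat extent + cell_size
# pm_path: pm25.csv                  # columns: date[,time],site_id,lat,lon,pm25
pm_min_hours: 1          # [choice] hourly PM records needed for a daily mean

run_cv: true             # leave-one-site-out CV of both panels
hist_bin_width: 10.0     # [choice] ug/m3, PM2.5 histogram comparison
log_level: INFO
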