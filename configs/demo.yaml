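# Full-size demonstration run: 500 px analysis boxes (the standard layout),
# disordered scar vs aligned flanks, published-moment morphometry, scar
# decay time-series, three simulated raters.  ~1 min on one CPU.
seed: 1
out_dir: results/demo
box_size: 500
gap: 20
n_fibers: 700
phantom_density: 0.35
scar_kappa: 0.5
flank_kappa: 5.0
n_per_group: 6
nac30_boost: 1.6
alpha: 0.05
write_images: true
write_heatmaps: true
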