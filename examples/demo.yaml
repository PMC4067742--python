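# End-to-end demo: simulate all three data types, then analyse them.
seed: 7
stages: [simulate, flim_fit, storm, morph, kinetics]

simulate:
  irf_fwhm_ns: 0.2
  n_channels: 256
  window_ns: 25.0
  flim:
    shape: [8, 8]
    tau_left_ns: 3.7        # monomer-like region
    tau_right_ns: 3.3       # fibril-like region
    photons_per_pixel: 500
    background_fraction: 0.05
  storm:
    kind: sphere
    size_nm: 160.0
    n_fluorophores: 120
    n_frames: 1000
    frame_shape: [32, 32]
    pixel_size_nm: 100.0
    psf_sigma_nm: 150.0
    photons_mean: 2000.0
    on_probability: 0.004
    background_rate: 2.0
  kinetics:
    L0: 3.7
    Linf: 3.3
    k: 2.0
    t50: 3.5
    noise_sd: 0.03

flim_fit:
  method: mle
  target_min: 3500
  target_max: 5000
  max_factor: 3

storm:
  threshold_k: 6.0
  bin_nm: 10.0

morph:
  min_count: 2
  resolution_nm: 55.0
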