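abundance_noise_sd: 0.3
background_level: 10.0
blob_intensity: 100.0
cluster_threshold: 150.0
condition: NA
crypt_depth: 60.0
crypt_pitch: 75.0
crypt_radius: 20.0
lattice_geometry: hex
lattice_nx: 18
lattice_ny: 18
mixing_matrix: null
n_spread_rounds: 2
noise_sd: 0.0
position_jitter_sd: 4.0
rng_seed: 0
sample_id: S1
seed_fraction: 0.06
spread_prob: 0.5
stained_ratio_mean: 200.0
stained_ratio_sd: 30.0
taxon_depth_means:
  Bacilli: 15.0
  Bacteroidetes: 45.0
  Clostridia: 28.0
taxon_depth_sds:
  Bacilli: 5.0
  Bacteroidetes: 5.0
  Clostridia: 5.0
type_archetypes:
  A:
    Bacilli: 8
    Bacteroidetes: 8
    Clostridia: 8
  B:
    Bacilli: 20
    Bacteroidetes: 25
    Clostridia: 420
  C:
    Bacilli: 320
    Bacteroidetes: 20
    Clostridia: 25
  D:
    Bacilli: 25
    Bacteroidetes: 520
    Clostridia: 400
  E:
    Bacilli: 20
    Bacteroidetes: 640
    Clostridia: 35
  F:
    Bacilli: 1300
    Bacteroidetes: 45
    Clostridia: 40
type_spatial_coupling: 1.0
voxel_size:
- 2.0
- 2.0
- 2.0
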