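# Fully synthetic end-to-end run: generate a colony-density scene, extract
# shadows by OBIA, census the colony from the shadow model, score the mask
# against the generator's truth, and compute the seasonal gas budget.
#
#   penguin-pipeline run --config examples/synthetic_colony.yaml --out-dir out/
scene_spec:
  n_penguins: 300
  image_size_px: [224, 224]
  resolution_m: 0.1
  sun_elevation_deg: 37.72
  penguin_height_m: 0.535
  penguin_width_m: 0.20
  channels: 1
  seed: 42
obia:
  scale: 15
  bi_threshold: 0.0
  mdi_threshold: 0.85
  review_area_px: 45
seed: 42
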