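# Replication scenario: Inexpressible Island Adélie colony surveys.
# The aerial photographs themselves are not distributed, so the shadow-pixel
# totals extracted from them act as the scene-level inputs; everything
# downstream (census, seasonal CH4/N2O budget, GWP) is recomputed.
#
# Run with:
#   python -c "
#   import yaml; from shadowcensus import replicate_census
#   cfg = yaml.safe_load(open('examples/inexpressible_island.yaml'))
#   for year, px in cfg['shadow_pixel_totals'].items():
#       print(year, replicate_census(px, cfg['pixels_per_penguin']))
#   "
shadow_pixel_totals:
  1983: 236253   # grayscale survey, 0.1-0.38 m resolution
  2012: 292323   # RGB survey, 0.1 m resolution
pixels_per_penguin: 13.8   # (H/tan alpha)*W/R^2 at H=53.5 cm, W=20 cm,
                           # alpha=37.72 deg, R=10 cm
guano:
  D: 84.5        # g dry guano per bird-day
  Mc: 1.8572     # moisture content, dry-weight basis (185.72%)
factors:
  ch4_c_range: [38.22, 219.60]   # ug CH4-C kg^-1 h^-1, aerobic incubation
  n2o_n_range: [0.45, 0.74]      # ug N2O-N kg^-1 h^-1
  conversion_mode: paper
season_days: 90
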