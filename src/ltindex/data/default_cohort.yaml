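# Default synthetic cohort: 13 cultivars across 4 tomato types, 152 fruits,
# SSC 3.0-8.5 °Brix, full 350-2500 nm grid at 1 nm, planted DSI signal at
# (805, 835) nm with target population R² 0.85.
blocks:
  - {name: "Gaofen No.1", tomato_type: large_red, n: 11, ssc_mean: 4.2, ssc_cv: 4.4, ssc_range: [4.0, 4.7]}
  - {name: "Mingzhi", tomato_type: large_red, n: 9, ssc_mean: 4.3, ssc_cv: 6.1, ssc_range: [3.9, 4.7]}
  - {name: "FQ581", tomato_type: large_red, n: 9, ssc_mean: 4.1, ssc_cv: 4.0, ssc_range: [3.7, 4.3]}
  - {name: "HTO-32", tomato_type: large_red, n: 8, ssc_mean: 4.0, ssc_cv: 3.6, ssc_range: [3.8, 4.2]}
  - {name: "HTO-40", tomato_type: large_red, n: 6, ssc_mean: 4.9, ssc_cv: 4.0, ssc_range: [4.6, 5.2]}
  - {name: "HTO-41", tomato_type: medium_red, n: 15, ssc_mean: 5.7, ssc_cv: 10.7, ssc_range: [4.8, 6.8]}
  - {name: "HTO-44", tomato_type: medium_red, n: 13, ssc_mean: 4.2, ssc_cv: 15.1, ssc_range: [3.0, 5.1]}
  - {name: "C575", tomato_type: medium_red, n: 12, ssc_mean: 3.6, ssc_cv: 6.5, ssc_range: [3.2, 4.0]}
  - {name: "Gaotianfen No.7", tomato_type: red_cherry, n: 15, ssc_mean: 7.0, ssc_cv: 4.9, ssc_range: [6.5, 7.5]}
  - {name: "HTO-47", tomato_type: red_cherry, n: 16, ssc_mean: 6.4, ssc_cv: 13.6, ssc_range: [5.1, 7.5]}
  - {name: "HTO-19", tomato_type: red_cherry, n: 12, ssc_mean: 7.2, ssc_cv: 4.3, ssc_range: [6.8, 7.7]}
  - {name: "HHTO-35", tomato_type: yellow_cherry, n: 10, ssc_mean: 7.0, ssc_cv: 5.8, ssc_range: [6.2, 7.7]}
  - {name: "HHTO-36", tomato_type: yellow_cherry, n: 16, ssc_mean: 7.2, ssc_cv: 12.0, ssc_range: [6.0, 8.5]}
planted:
  family: DSI
  bands: [805.0, 835.0]
  slope: 20.0
  intercept: 5.5
  target_r2: 0.85
grid: [350.0, 2500.0, 1.0]
rng_seed: 0
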