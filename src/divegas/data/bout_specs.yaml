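# Per-animal dive-bout statistics used by the synthetic bout generator:
# for each depth bin, the proportion of dives (%), dive duration mean +/- SD
# (s) and maximum-depth mean +/- SD (m).  Bins: shallow < 30 m,
# medium 30-90 m, deep > 90 m.  A null bin means no dives of that class.
# body_mass in kg.  Cm3's deep class was a single 944 s / 90.5 m dive
# (<0.01% of dives) and is carried with sd 0.
version: 1
animals:
  Dc1:
    species: leatherback
    body_mass: 334
    shallow: {proportion: 87.2, duration: [209, 251], max_depth: [6.3, 7.0]}
    medium:  {proportion: 11.6, duration: [827, 157], max_depth: [49.1, 14.4]}
    deep:    {proportion: 1.2,  duration: [839, 97],  max_depth: [108.7, 15.3]}
  Dc2:
    species: leatherback
    body_mass: 356
    shallow: {proportion: 90.3, duration: [177, 222], max_depth: [4.1, 5.3]}
    medium:  {proportion: 6.5,  duration: [1155, 248], max_depth: [55.5, 18.6]}
    deep:    {proportion: 3.2,  duration: [1345, 141], max_depth: [136.4, 88.3]}
  Dc3:
    species: leatherback
    body_mass: 392
    shallow: {proportion: 84.0, duration: [74, 138],  max_depth: [9.5, 7.0]}
    medium:  {proportion: 14.2, duration: [244, 349], max_depth: [51.3, 15.8]}
    deep:    {proportion: 1.9,  duration: [367, 473], max_depth: [134.1, 67.8]}
  Dc4:
    species: leatherback
    body_mass: 217
    shallow: {proportion: 75.0, duration: [175, 162], max_depth: [7.8, 8.0]}
    medium:  {proportion: 23.2, duration: [581, 161], max_depth: [48.2, 13.8]}
    deep:    {proportion: 1.8,  duration: [812, 133], max_depth: [120.7, 36.9]}
  Dc5:
    species: leatherback
    body_mass: 371
    shallow: {proportion: 71.7, duration: [230, 231], max_depth: [9.3, 9.4]}
    medium:  {proportion: 25.0, duration: [775, 234], max_depth: [49.5, 15.2]}
    deep:    {proportion: 3.2,  duration: [1166, 211], max_depth: [114.3, 20.0]}
  Dc6:
    species: leatherback
    body_mass: 360
    shallow: {proportion: 92.8, duration: [156, 174], max_depth: [4.3, 5.5]}
    medium:  {proportion: 6.2,  duration: [911, 199], max_depth: [54.9, 15.9]}
    deep:    {proportion: 0.9,  duration: [1063, 98], max_depth: [115.9, 38.7]}
  Cc1:
    species: loggerhead
    body_mass: 44
    shallow: {proportion: 97.3, duration: [150, 499], max_depth: [0.7, 1.9]}
    medium:  {proportion: 2.7,  duration: [1396, 604], max_depth: [44.6, 6.5]}
    deep: null
  Cc2:
    species: loggerhead
    body_mass: 89
    shallow: {proportion: 94.2, duration: [181, 396], max_depth: [1.1, 2.3]}
    medium:  {proportion: 5.8,  duration: [1685, 840], max_depth: [53.3, 7.5]}
    deep: null
  Cc3:
    species: loggerhead
    body_mass: 60
    shallow: {proportion: 93.9, duration: [256, 544], max_depth: [1.0, 2.1]}
    medium:  {proportion: 6.1,  duration: [2117, 439], max_depth: [66.3, 8.9]}
    deep: null
  Cm1:
    species: green
    body_mass: 71
    shallow: {proportion: 88.0, duration: [183, 438], max_depth: [2.3, 4.4]}
    medium:  {proportion: 10.7, duration: [2705, 1215], max_depth: [58.1, 17.7]}
    deep:    {proportion: 1.2,  duration: [3106, 891], max_depth: [96.9, 6.5]}
  Cm2:
    species: green
    body_mass: 81
    shallow: {proportion: 96.1, duration: [502, 542], max_depth: [5.0, 5.1]}
    medium:  {proportion: 3.9,  duration: [1314, 479], max_depth: [48.4, 9.7]}
    deep: null
  Cm3:
    species: green
    body_mass: 65
    shallow: {proportion: 97.6, duration: [324, 382], max_depth: [4.6, 5.0]}
    medium:  {proportion: 2.4,  duration: [892, 390], max_depth: [44.2, 11.1]}
    deep:    {proportion: 0.005, duration: [944, 0], max_depth: [90.5, 0]}
  Cm4:
    species: green
    body_mass: 70
    shallow: {proportion: 100.0, duration: [431, 500], max_depth: [2.4, 1.8]}
    medium: null
    deep: null
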