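{
 "density_g_cm3": {
  "water": 1.0,
  "aluminium": 2.699,
  "beryllium": 1.848,
  "air": 0.00120479,
  "tungsten": 19.3
 },
 "z_over_a": {
  "water": 0.55508,
  "aluminium": 0.48181,
  "beryllium": 0.44384,
  "air": 0.49919,
  "tungsten": 0.4025
 }
}
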