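# Published child:adult maturation-ratio curves (postnatal age in days).
# Each curve is pinned to exactly 1 at and beyond cap_age.
sc_thickness:
  model1:
    form: polynomial
    coefficients: {a: 2.401e-7, n: 2.000, b: -99.43, m: 2.071e-3, c: 101.4}
    cap_age: 1510
  model2:
    form: power
    coefficients: {a: 2.662e-7, b: 1.878, c: 0.724}
    cap_age: 1604
ed_thickness:
  form: hill
  coefficients: {a: 0.366, b: 18.702, n: 5.363, c: 0.634}
  cap_age: null
de_thickness:
  form: sigmoid
  coefficients: {a: 1.093, b: 8974, c: 0.407}
  cap_age: 9883
sc_hydration:
  form: polynomial
  coefficients: {a: -0.344, n: 0.245, b: -17.585, m: -0.0171, c: 18.530}
  cap_age: 1182
  min_age: 1
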