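{
  "reference": "Chen-Millero-type limnological equation of state (freshwater polynomial with dilute-salinity and pressure corrections)",
  "rho0_coeffs": [999.8395, 6.7914e-2, -9.0894e-3, 1.0171e-4, -1.2846e-6, 1.1592e-8, -5.0125e-11],
  "salinity_coeffs": [0.8181, -3.85e-3, 4.96e-5],
  "bulk_modulus": {
    "k0_coeffs": [19652.17, 148.113, -2.293, 1.256e-2, -4.18e-5],
    "kp_coeffs": [3.2726, -2.147e-4, 1.128e-4],
    "ks_coeffs": [53.238, -0.313, 5.728e-3],
    "pressure_unit": "bar"
  },
  "cp0_coeffs": [4217.4, -3.720283, 0.1412855, -2.654387e-3, 2.093236e-5],
  "cps_coeffs": [-7.6444, 0.107276, -1.3839e-3],
  "valid_range": {"T_c": [-1.0, 40.0], "S_g_per_l": [0.0, 10.0], "p_dbar": [0.0, 500.0]}
}
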