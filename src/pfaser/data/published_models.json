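{
  "_comment": "The four published descriptor->pIC50 equations. 'coefficients' are raw (per descriptor unit); 'normalized_coefficients' are raw * SD(descriptor) as published. TB = top binders, CE = commonly exposed.",
  "_descriptor_order": ["Number of H-Bond Acceptors", "Number of H-Bond Donors", "LogD (pH 7.4)", "Average Mass", "Density", "F+ Max", "HOMO", "LUMO", "Polar Surface Area", "Surface Tension", "Number of Freely Rotating Bonds"],
  "TB-ERalpha": {
    "descriptor_names": ["Number of H-Bond Acceptors", "Number of H-Bond Donors", "LogD (pH 7.4)", "Average Mass", "Density", "F+ Max", "HOMO", "LUMO", "Polar Surface Area", "Surface Tension", "Number of Freely Rotating Bonds"],
    "coefficients": [0.0154, -0.0312, 0.0485, 0.2222, 0.0887, 0.0166, -0.0198, 0.0285, -0.0185, -0.0821, -0.3843],
    "normalized_coefficients": [0.0408, -0.0322, 0.2422, 49.2514, 0.0219, 0.0011, -0.0449, 0.0434, -0.9347, -1.3549, -2.3991],
    "intercept": 8.03
  },
  "TB-ERbeta": {
    "descriptor_names": ["Number of H-Bond Acceptors", "Number of H-Bond Donors", "LogD (pH 7.4)", "Average Mass", "Density", "F+ Max", "HOMO", "LUMO", "Polar Surface Area", "Surface Tension", "Number of Freely Rotating Bonds"],
    "coefficients": [0.0857, 0.0395, 0.2245, 0.1336, 0.1731, -0.0471, -0.0218, 0.1132, 0.0069, -0.0635, -0.481],
    "normalized_coefficients": [0.1842, 0.0363, 0.8252, 30.1649, 0.042, -0.0048, -0.0459, 0.1306, 0.2707, -1.3352, -3.3561],
    "intercept": 8.02
  },
  "CE-ERalpha": {
    "descriptor_names": ["Number of H-Bond Acceptors", "Number of H-Bond Donors", "LogD (pH 7.4)", "Average Mass", "Density", "F+ Max", "HOMO", "LUMO", "Polar Surface Area", "Surface Tension", "Number of Freely Rotating Bonds"],
    "coefficients": [-0.2744, -0.0874, 0.0483, -0.0198, 0.39, -0.0485, 0.1857, 0.0316, 0.4216, -0.4753, 0.2519],
    "normalized_coefficients": [-0.4964, -0.0487, 0.1923, -4.1092, 0.0513, -0.0043, 0.7999, 0.1539, 10.6211, -2.3411, 1.037],
    "intercept": 5.95
  },
  "CE-ERbeta": {
    "descriptor_names": ["Number of H-Bond Acceptors", "Number of H-Bond Donors", "LogD (pH 7.4)", "Average Mass", "Density", "F+ Max", "HOMO", "LUMO", "Polar Surface Area", "Surface Tension", "Number of Freely Rotating Bonds"],
    "coefficients": [-0.178, -0.0343, -0.0835, 0.0344, 0.3057, 0.0343, 0.0242, 0.0734, 0.1504, -0.2855, 0.5858],
    "normalized_coefficients": [-0.3563, -0.0212, -0.3679, 7.8995, 0.0445, 0.0034, 0.1153, 0.3954, 4.1924, -1.556, 2.6684],
    "intercept": 6.02
  }
}
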