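{
  "schema_version": 1,
  "description": "One classifier of the published 1000-member ensemble for healthy controls vs all MDD: per-class linear discriminant scores C1 (control) and MDD1 (case) over the 9-metabolite feature panel.",
  "class_labels": ["HEALTHY", "MDD_ALL"],
  "feature_names": [
    "Valine",
    "Leucine",
    "Proline",
    "Glyceric acid",
    "Pyroglutamate",
    "Galactose",
    "Glucopyranose",
    "Palmitic acid",
    "Heptadecylic acid"
  ],
  "control_intercept": -193.22739,
  "control_coefficients": [-348.65282, 637.70420, 37.96944, 771.28313, -179.95208, -21.87057, 82.37111, 281.58456, 3245.21105],
  "case_intercept": -143.65828,
  "case_coefficients": [-251.96156, 453.25011, 31.32127, 475.62189, -117.87757, -10.38482, 68.85657, 224.79745, 2492.61184]
}
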