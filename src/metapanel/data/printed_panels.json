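{
  "schema_version": 1,
  "description": "Published diagnostic panels: 'differential' panels are nested-logistic/ROC panels over VIP-ranked differential metabolites; 'tclass' panels are feature-metabolite combinations chosen by forward selection with LOOCV. Member lists in published order.",
  "panels": [
    {
      "comparison": ["HEALTHY", "MDD_ALL"],
      "method": "differential",
      "metabolites": ["Linoleic acid", "Cholesterol", "Glycine", "Galactose", "Alanine", "Oleic acid", "Heptadecylic acid", "Myoinositol", "Sorbitol"]
    },
    {
      "comparison": ["HEALTHY", "ELS_MDD"],
      "method": "differential",
      "metabolites": ["Aspartic acid", "Glycine", "Linoleic acid", "Sorbitol", "Myoinositol", "Mannose", "6-deoxy-mannopyrannose", "Oleic acid", "Alanine"]
    },
    {
      "comparison": ["HEALTHY", "NON_ELS_MDD"],
      "method": "differential",
      "metabolites": ["Cholesterol", "Linoleic acid", "Glycine"]
    },
    {
      "comparison": ["ELS_MDD", "NON_ELS_MDD"],
      "method": "differential",
      "metabolites": ["Cholesterol", "Glucopyranose", "Linoleic acid", "Glyceric acid"]
    },
    {
      "comparison": ["HEALTHY", "MDD_ALL"],
      "method": "tclass",
      "learner": "naive_bayes",
      "metabolites": ["Valine", "Leucine", "Proline", "Glyceric acid", "Pyroglutamate", "Galactose", "Glucopyranose", "Palmitic acid", "Heptadecylic acid"]
    },
    {
      "comparison": ["HEALTHY", "ELS_MDD"],
      "method": "tclass",
      "metabolites": ["Lactic acid", "Proline", "Glyceric acid", "Mannose", "Gluconate", "Tryptophane", "Stearic acid", "Cholesterol"]
    },
    {
      "comparison": ["HEALTHY", "NON_ELS_MDD"],
      "method": "tclass",
      "metabolites": ["6-deoxy-mannopyrannose", "Palmitic acid", "Heptadecylic acid"]
    },
    {
      "comparison": ["ELS_MDD", "NON_ELS_MDD"],
      "method": "tclass",
      "metabolites": ["Oxalic acid", "Heptadecylic acid", "Stearic acid"]
    }
  ]
}
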