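{
  "baseline_utilities.csv": {
    "rows": 101,
    "sha256": "e2e7b20ee904d777909100f6239fa267c603ae94cc0ce029119662f8ad34be0b"
  },
  "disease_costs.csv": {
    "rows": 11,
    "sha256": "3ed6dfd05a8b8069d3ec3b2c00b1b59c92f8c6260ff380ae21afd3f8272aa760"
  },
  "intermediate_effects.csv": {
    "rows": 7,
    "sha256": "4712ced6851a7b1d603d95498de557c0b11f1a97efd0f2ed19e28a62b0f3da63"
  },
  "mediation.csv": {
    "rows": 10,
    "sha256": "88fe41ec75e5fb1ec0d3be43331852ef1d419723adab2b690a12e4c27d3dc996"
  },
  "relative_risks.csv": {
    "rows": 61,
    "sha256": "b2c55fade6bc6eaf5641d60ea828766eb9738f3bc2c63df9502a30c829df9977"
  },
  "theoretical_minima.csv": {
    "rows": 9,
    "sha256": "3636cbddc78b34eae258a36d320fe128a935053f9508079fae6833ea8ab6a47b"
  },
  "unrelated_costs_synthetic.csv": {
    "rows": 202,
    "sha256": "e50d96191d681001189b8fee2050942c7e8de426a8ed645a20e4e704e2618d46"
  },
  "utility_decrements.csv": {
    "rows": 13,
    "sha256": "62671103afc6dd2b9aba58b5aa57f095dad6ead826ff09aae8406740db605233"
  }
}
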