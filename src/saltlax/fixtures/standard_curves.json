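[
  {"analyte": "glycyrrhizic acid", "slope": 87.2, "intercept": -3.76, "low": 1.0, "high": 1000.0, "units": "ng/mL"},
  {"analyte": "glycyrrhetinic acid", "slope": 136.8, "intercept": -122.4, "low": 1.0, "high": 1000.0, "units": "ng/mL"},
  {"analyte": "liquiritin", "slope": 750.9, "intercept": 356.9, "low": 1.0, "high": 1000.0, "units": "ng/mL"},
  {"analyte": "liquiritigenin", "slope": 509.2, "intercept": 925.6, "low": 1.0, "high": 1000.0, "units": "ng/mL"},
  {"analyte": "isoliquiritigenin", "slope": 8775.1, "intercept": 2617.0, "low": 1.0, "high": 1000.0, "units": "ng/mL"},
  {"analyte": "total flavonoids", "slope": 0.026, "intercept": -0.056, "low": 0.0, "high": 32.0, "units": "ug/mL"}
]
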