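{
  "comment": "Published population-average motor-threshold values used to validate the model. Only quantities printed as numbers in the source reports are included; strength-duration means that exist only as figure panels are deliberately absent (no desk-verifiable numbers to package). RMT is typically about 10 percentage points of stimulator output above AMT.",
  "rmt_amt_offset_pct_mso": 10.0,
  "records": [
    {
      "label": "#1RMT 60us m0.2 unidirectional AP",
      "measure": "RMT",
      "value": 32.0,
      "units": "%MSO",
      "provenance": "printed-in-text",
      "source": "ctms-paired-pulse-plasticity-study"
    },
    {
      "label": "ThPW at 120% #1RMT",
      "measure": "ThPW",
      "value": 47.3,
      "units": "us",
      "provenance": "printed-in-text",
      "source": "ctms-paired-pulse-plasticity-study"
    }
  ]
}
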