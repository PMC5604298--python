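{
  "month": ["date"],
  "year": ["date"],
  "disease": ["illness", "sickness"],
  "gender": ["sex"],
  "tissue": ["organ"],
  "strain": ["background"],
  "treatment": ["therapy"],
  "stage": ["phase"],
  "time": ["duration"],
  "patient": ["subject", "donor"],
  "sample": ["specimen"],
  "origin": ["source"],
  "isolated": ["separated"],
  "derived": ["obtained"],
  "weight": ["mass"],
  "location": ["site"]
}
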