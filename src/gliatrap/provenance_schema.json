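{
  "title": "gliatrap pipeline provenance record",
  "required": {
    "inputs": {"type": "object"},
    "thresholds": {"type": "object"},
    "seed": {"type": "integer"},
    "version": {"type": "string"},
    "stages_run": {"type": "array"}
  }
}
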