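{
  "description": "Minimal schema for per-stage JSON summaries. Each summary object must carry the stage name and a counts mapping of non-negative integers; any other keys must be numbers, strings or booleans.",
  "required": ["stage", "counts"],
  "types": {
    "stage": "str",
    "counts": "dict[str,int>=0]"
  }
}
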