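{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "serpinscope report",
  "type": "object",
  "required": ["tool", "version", "command", "config", "inputs", "results"],
  "properties": {
    "tool": {"type": "string", "const": "serpinscope"},
    "version": {"type": "string"},
    "command": {"type": "string"},
    "config": {"type": "object"},
    "inputs": {
      "type": "object",
      "additionalProperties": {"type": "string", "pattern": "^[0-9a-f]{64}$"}
    },
    "results": {"type": "object"}
  }
}
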