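{
 "required": {"seed": "int", "targets": "list", "all_pass": "bool"},
 "target_required": {"id": "str", "measured": "float", "expected": "float",
                     "cmp": "str", "pass": "bool"}
}
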