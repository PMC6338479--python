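"""Build a BCO in memory, validate it, seal it, and detect tampering.

The seal is a SHA-256 digest over the canonical bytes (sorted keys, no
whitespace, signature field excluded), so it is stable across member
reordering but breaks on any content change.
"""

from bcokit import forge, parse_bco, emit_json, seal_envelope, verify_seal, validate_envelope

env = forge.forge_minimal_envelope()
report = validate_envelope(env)
print(f"validation findings: {len(report.findings)}  (0 means every "
      f"structural and semantic invariant holds)")

sealed = seal_envelope(env)
print(f"digital signature: {sealed.digital_signature}")
print(f"seal verifies:     {verify_seal(sealed)}")

# round-trip through JSON text does not disturb the seal
again, _ = parse_bco(emit_json(sealed))
print(f"after JSON round-trip, still verifies: {verify_seal(again)}")

# but any content edit breaks it
again.provenance.version = "1.0.1"
print(f"after editing the version field:       {verify_seal(again)}  "
      f"(the document no longer matches its seal)")
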