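"""Cysteine-signature extraction and subclass assignment for single
proteins, with per-constraint diagnostics.

A classic OBP carries six conserved cysteines spaced
C1-X22-32-C2-X3-C3-X30-47-C4-X8-10-C5-X8-C6; a CSP carries four spaced
C1-X6-C2-X18-C3-X2-C4.
"""

import chemokit as ck

def build(gaps, lead=4, tail=15):
    parts = ["A" * lead]
    for g in gaps:
        parts += ["C", "A" * g]
    parts.append("C")
    return "".join(parts) + "A" * tail

for name, gaps in [("classic-like", [25, 3, 40, 9, 8]),
                   ("minus-C-like", [32, 40, 18]),
                   ("CSP-like", [6, 18, 2])]:
    mature = build(gaps)
    sig = ck.cys_signature(mature)
    strict = ck.assign_class(sig, mature, mode="strict")
    count = ck.assign_class(sig, mature, mode="count_based")
    print(f"{name}: {sig.count} cysteines, spacings {sig.spacings}")
    print(f"  count-based -> {count.label}; strict -> {strict.label}")
    print(f"  strict diagnostics: {strict.diagnostics}")
# The diagnostics show which inter-cysteine gap satisfied which range,
# so a strict-mode rejection is attributable to a single spacing.
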