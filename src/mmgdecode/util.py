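"""Small shared helpers: deterministic child-seed derivation."""

from __future__ import annotations

_MOD = 2**31


def child_seed(master: int, *keys: int) -> int:
    """Derive a child seed from a master seed by fixed integer arithmetic.

    Folding each key with a large prime multiplier keeps children deterministic,
    distinct for distinct key paths, and below 2**31.
    """
    h = int(master) % _MOD
    for k in keys:
        h = (h * 1000003 + int(k) + 1) % _MOD
    return h
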