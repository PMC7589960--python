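"""Deterministic seed derivation.

A single user-facing seed is fanned out to per-stage sub-seeds with a
splitmix64 round over ``seed XOR crc32(label)`` so each stage is
independently reproducible from (seed, stage name).
"""

from __future__ import annotations

import zlib

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (x ^ (x >> 31)) & _MASK64


def child_seed(seed: int, label: str) -> int:
    """Derive a 31-bit sub-seed for ``label`` from a master seed."""
    x = (int(seed) ^ zlib.crc32(label.encode("utf-8"))) & _MASK64
    return _splitmix64(x) >> 33
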