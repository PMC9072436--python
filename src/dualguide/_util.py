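"""Small shared helpers: DNA string ops and seeded RNG splitting."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA_ALPHABET = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (ACGT/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def validate_spacer(spacer: str, length: int) -> None:
    if len(spacer) != length:
        raise ValueError(f"spacer must be {length} nt, got {len(spacer)} ({spacer!r})")
    if set(spacer) - set(DNA_ALPHABET):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")


def split_rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-based RNG splitting: one master seed, independent sub-streams.

    Every stochastic stage of the pipeline draws from its own stream so that,
    e.g., regenerating reads does not perturb the count draw.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# stable stream ids for the simulator's stages
STREAM_LIBRARY = 0
STREAM_COUNTS = 1
STREAM_READS = 2
STREAM_COHORT = 3
STREAM_GUIDE_MATRIX = 4
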