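"""Small shared helpers: alphabets, complements, seeded RNG derivation."""

from __future__ import annotations

import numpy as np

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA sequence (ACGUN)."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def spawn_rng(seed: int, *salt: int) -> np.random.Generator:
    """Derive an independent, reproducible generator from a base seed.

    ``salt`` integers key sub-streams (condition index, contig index,
    replicate number ...) so that adding replicates never perturbs
    earlier streams.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=salt))
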