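"""Genetic-code tables and codon-level change enumeration.

Everything downstream (consequence annotation, opportunity counting,
context collapsing) is driven by a handful of dense integer lookup
tables built once at import time from the standard genetic code
(Biopython's table 1).  Bases are encoded A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: consequence codes
SYNONYMOUS, MISSENSE, OTHER = 0, 1, 2
CONSEQUENCE_NAMES = {SYNONYMOUS: "synonymous", MISSENSE: "missense", OTHER: "other"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

CODONS = ["".join((a, b, c)) for a in BASES for b in BASES for c in BASES]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def codon_index(codon: str) -> int:
    """Dense index of a codon in base-4 order (AAA=0 ... TTT=63)."""
    return (
        16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]
    )


def _aa(codon: str) -> str | None:
    if codon in STOP_CODONS:
        return None
    return _STANDARD.forward_table[codon]


def _build_consequence_table() -> np.ndarray:
    """table[codon_idx, pos, alt_base] -> consequence code, or -1.

    -1 marks impossible cells: alt equals the reference base at that
    position, or the reference codon itself is a stop codon.
    """
    table = np.full((64, 3, 4), -1, dtype=np.int8)
    for codon in CODONS:
        ci = codon_index(codon)
        if codon in STOP_CODONS:
            continue
        aa_ref = _aa(codon)
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    cons = OTHER  # stop-gain
                elif _aa(mutant) == aa_ref:
                    cons = SYNONYMOUS
                else:
                    cons = MISSENSE
                table[ci, pos, BASE_INDEX[alt]] = cons
    return table


#: CONSEQUENCE_TABLE[codon_idx, position_in_codon, alt_base_idx]
CONSEQUENCE_TABLE = _build_consequence_table()


def consequence(codon: str, pos_in_codon: int, alt: str) -> int:
    """Consequence code of substituting ``alt`` at ``pos_in_codon`` (0-based)."""
    if codon in STOP_CODONS:
        raise ValueError(f"reference codon {codon} is a stop codon")
    code = CONSEQUENCE_TABLE[codon_index(codon), pos_in_codon, BASE_INDEX[alt]]
    if code < 0:
        raise ValueError(f"alt base {alt} equals reference at position {pos_in_codon}")
    return int(code)


def count_codon_changes(codon: str) -> tuple[int, int, int]:
    """Partition the 9 single-nucleotide changes of a sense codon.

    Returns (n_missense, n_synonymous, n_other) where "other" counts
    stop-gain changes.  Raises on a stop codon input.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    if len(codon) != 3 or any(b not in BASE_INDEX for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    row = CONSEQUENCE_TABLE[codon_index(codon)]
    n_mis = int((row == MISSENSE).sum())
    n_syn = int((row == SYNONYMOUS).sum())
    n_other = int((row == OTHER).sum())
    assert n_mis + n_syn + n_other == 9
    return n_mis, n_syn, n_other


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0..T=3); raises on other bases."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = chr(arr[int(np.argmax(out < 0))])
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return out
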