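"""Trinucleotide-context mutation spectrum and opportunity counting.

The neutral mutation model has 96 relative-rate parameters: the six
pyrimidine-centred single-base substitutions (C>A, C>G, C>T, T>A, T>C,
T>G) times the 4 x 4 flanking-base combinations.  Substitutions whose
reference base is a purine are folded onto the pyrimidine strand by
reverse-complementing the trinucleotide and the change.

The spectrum is estimated from synonymous mutations only (assumed
neutral) and is used to weight every possible coding change when
computing a transcript's expected nonsynonymous and synonymous site
counts L_N and L_S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import (
    BASES,
    BASE_INDEX,
    CONSEQUENCE_TABLE,
    MISSENSE,
    SYNONYMOUS,
    encode_sequence,
)

logger = logging.getLogger(__name__)

N_CLASSES = 96

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

#: pyrimidine-centred substitutions in canonical order
SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_SUB_INDEX = {
    (BASE_INDEX[r], BASE_INDEX[a]): i for i, (r, a) in enumerate(SUBSTITUTIONS)
}


def _build_context_table() -> np.ndarray:
    """table[f5, ref, alt, f3] -> class index 0..95 (-1 where ref == alt)."""
    table = np.full((4, 4, 4, 4), -1, dtype=np.int16)
    for f5 in range(4):
        for ref in range(4):
            for alt in range(4):
                if ref == alt:
                    continue
                for f3 in range(4):
                    r, a, l5, l3 = ref, alt, f5, f3
                    if (r, a) not in _SUB_INDEX:  # purine reference: fold
                        r, a = _COMPLEMENT[r], _COMPLEMENT[a]
                        l5, l3 = _COMPLEMENT[f3], _COMPLEMENT[f5]
                    table[f5, ref, alt, f3] = _SUB_INDEX[(r, a)] * 16 + l5 * 4 + l3
    return table


#: CONTEXT_TABLE[f5, ref, alt, f3] with bases encoded A=0..T=3
CONTEXT_TABLE = _build_context_table()

CLASS_NAMES = [
    f"{BASES[f5]}[{r}>{a}]{BASES[f3]}"
    for (r, a) in SUBSTITUTIONS
    for f5 in range(4)
    for f3 in range(4)
]
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


def collapse_context(flank5: str, ref: str, alt: str, flank3: str) -> str | None:
    """Collapse a flanked substitution onto its pyrimidine-centred class name.

    Returns ``None`` when any base is ambiguous (e.g. N); raises if
    ref == alt.
    """
    bases = (flank5.upper(), ref.upper(), alt.upper(), flank3.upper())
    if any(b not in BASE_INDEX for b in bases):
        return None
    f5, r, a, f3 = (BASE_INDEX[b] for b in bases)
    if r == a:
        raise ValueError("ref and alt bases are identical")
    return CLASS_NAMES[CONTEXT_TABLE[f5, r, a, f3]]


@dataclass
class ContextSpectrum:
    """96 relative mutation rates, normalised to mean 1."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_CLASSES,):
            raise ValueError(f"spectrum must have {N_CLASSES} rates")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("spectrum rates must be finite and non-negative")

    @classmethod
    def uniform(cls) -> "ContextSpectrum":
        return cls(np.ones(N_CLASSES))

    def normalized(self) -> "ContextSpectrum":
        mean = self.rates.mean()
        if mean <= 0:
            raise ValueError("cannot normalise an all-zero spectrum")
        return ContextSpectrum(self.rates / mean)

    def rate(self, class_name: str) -> float:
        return float(self.rates[CLASS_INDEX[class_name]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context_class": CLASS_NAMES, "rate": self.rates})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ContextSpectrum":
        df = pd.read_csv(path, sep="\t")
        rates = np.empty(N_CLASSES)
        lookup = dict(zip(df["context_class"], df["rate"]))
        for i, name in enumerate(CLASS_NAMES):
            rates[i] = lookup[name]
        return cls(rates)


@dataclass
class OpportunityCounts:
    """Rate-weighted expected site counts for one transcript."""

    L_N: float
    L_S: float
    #: per-class counts of possible synonymous / nonsynonymous changes
    syn_by_class: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    nonsyn_by_class: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    @property
    def ratio(self) -> float:
        return self.L_N / self.L_S


def _coding_change_arrays(cds_sequence: str, n_codons: int):
    """Vectorised enumeration of all single-nucleotide coding changes.

    Returns (consequence, context_class) int arrays of shape
    (3*n_codons, 3): one row per coding position, one column per
    alternative base (in base order, skipping the reference).  Context
    class is -1 where a flank is unavailable (transcript edges).
    """
    seq = encode_sequence(cds_sequence)
    n = 3 * n_codons
    pos = np.arange(n)
    ref = seq[:n]
    f5 = np.full(n, -1, dtype=np.int64)
    f5[1:] = seq[: n - 1]
    f3 = np.full(n, -1, dtype=np.int64)
    f3[: min(n, len(seq) - 1)] = seq[1 : n + 1]

    codon_idx = (
        16 * seq[3 * (pos // 3)] + 4 * seq[3 * (pos // 3) + 1] + seq[3 * (pos // 3) + 2]
    ).astype(np.int64)
    pos_in_codon = pos % 3

    # the three alternative bases for each position
    alts = np.empty((n, 3), dtype=np.int64)
    for i in range(4):
        mask = ref == i
        alts[mask] = [b for b in range(4) if b != i]

    cons = np.empty((n, 3), dtype=np.int64)
    ctx = np.empty((n, 3), dtype=np.int64)
    for j in range(3):
        cons[:, j] = CONSEQUENCE_TABLE[codon_idx, pos_in_codon, alts[:, j]]
        known = (f5 >= 0) & (f3 >= 0)
        ctx[:, j] = -1
        ctx[known, j] = CONTEXT_TABLE[f5[known], ref[known], alts[known, j], f3[known]]
    return cons, ctx


def expected_sites(transcript, spectrum: ContextSpectrum) -> OpportunityCounts:
    """Compute L_N and L_S for a transcript under a context spectrum.

    L_N sums the spectrum rate of every possible nonsynonymous
    single-nucleotide change over the coding positions (terminal stop
    codon excluded); L_S likewise for synonymous changes.  Stop-gain
    changes contribute to neither.  Changes at transcript edges with an
    unknown flank use rate 1 (the spectrum mean).
    """
    cons, ctx = _coding_change_arrays(transcript.cds_sequence, transcript.n_codons)
    rates = np.where(ctx >= 0, spectrum.rates[np.clip(ctx, 0, None)], 1.0)

    mis = cons == MISSENSE
    syn = cons == SYNONYMOUS
    L_N = float(rates[mis].sum())
    L_S = float(rates[syn].sum())

    syn_by_class = np.bincount(ctx[syn & (ctx >= 0)], minlength=N_CLASSES).astype(float)
    nonsyn_by_class = np.bincount(
        ctx[mis & (ctx >= 0)], minlength=N_CLASSES
    ).astype(float)
    return OpportunityCounts(L_N, L_S, syn_by_class, nonsyn_by_class)


def synonymous_opportunities(transcripts) -> np.ndarray:
    """Total per-class synonymous change counts across transcripts."""
    total = np.zeros(N_CLASSES)
    for tx in transcripts:
        cons, ctx = _coding_change_arrays(tx.cds_sequence, tx.n_codons)
        syn = (cons == SYNONYMOUS) & (ctx >= 0)
        total += np.bincount(ctx[syn], minlength=N_CLASSES)
    return total


def estimate_context_rates(
    synonymous_records: pd.DataFrame,
    transcripts,
    pseudocount: float = 0.5,
) -> ContextSpectrum:
    """Estimate the 96-class spectrum from cohort synonymous mutations.

    rate[c] is proportional to (observed synonymous mutations in class c
    + pseudocount) / (synonymous opportunities in class c + pseudocount),
    normalised to mean 1.  Records without a context class are ignored.
    """
    classes = synonymous_records["context_class"].dropna()
    if len(classes) == 0:
        raise ValueError("no synonymous mutations with a context class")
    obs = np.zeros(N_CLASSES)
    for name, count in classes.value_counts().items():
        obs[CLASS_INDEX[name]] += count
    opp = synonymous_opportunities(transcripts)
    empty = opp == 0
    if empty.any():
        logger.warning(
            "%d context classes have zero synonymous opportunities; "
            "their rates fall back to the neutral prior (relative rate 1)",
            int(empty.sum()),
        )
    rates = np.ones(N_CLASSES)
    pos = ~empty
    if not pos.any():
        logger.warning("no synonymous opportunities at all; uniform spectrum")
        return ContextSpectrum(rates)
    raw = (obs[pos] + pseudocount) / (opp[pos] + pseudocount)
    # classes without opportunities are uninformative: they keep the
    # prior relative rate 1, on the same scale as the observed classes
    rates[pos] = raw / raw.mean()
    return ContextSpectrum(rates).normalized()
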