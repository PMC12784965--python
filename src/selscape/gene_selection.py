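"""Gene-level selection statistics: C_N/C_S, H and the chi-square tests.

C_N/C_S = (N/L_N)/(S/L_S) compares observed missense and synonymous
mutation counts against their rate-weighted site opportunities.  H
measures among-site rate heterogeneity from the per-codon missense
count vector z:

    H = (var(z) - zbar) / (var(z) + zbar*(zbar - 1)),  clamped to [0, 1]

which is the moment estimator of 1 - (E[lambda])^2 / E[lambda^2] for
the latent per-site rates.  Genes are tested against the neutral ratio
1 and against the heterogeneity-adjusted ratio 1-H with a two-cell
Pearson goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .spectrum import OpportunityCounts


class SelectionMode(str, Enum):
    DOMINANT_POSITIVE = "dominant_positive"
    WEAK_POSITIVE = "weak_positive"
    NEGATIVE = "negative"
    NEUTRAL_OR_UNDETERMINED = "neutral_or_undetermined"


@dataclass
class GeneCounts:
    """Observed mutation counts of one gene."""

    gene_id: str
    N: int  # missense mutations
    S: int  # synonymous mutations
    S_N: int  # distinct codons with >=1 missense mutation
    S_S: int  # distinct CDS positions with >=1 synonymous mutation
    z: np.ndarray  # per-codon missense counts, length n_codons

    @property
    def n_codons(self) -> int:
        return len(self.z)


@dataclass
class GeneSelectionStats:
    gene_id: str
    cncs: float
    H: float
    p_vs_1: float
    p_vs_1mH: float
    mode: SelectionMode
    flags: tuple[str, ...] = ()


def tally_gene(records: pd.DataFrame, transcript) -> GeneCounts:
    """Tally N, S, S_N, S_S and the per-codon z vector for one gene.

    ``records`` holds annotated mutations of this gene only; every
    mutation (from any sample) increments its codon's z entry.
    """
    z = np.zeros(transcript.n_codons, dtype=np.int64)
    if len(records):
        bad = records["gene_id"] != transcript.gene_id
        if bad.any():
            raise ValueError("records from a different gene passed to tally_gene")
    mis = records[records["consequence"] == "missense"]
    syn = records[records["consequence"] == "synonymous"]
    if len(mis):
        np.add.at(z, mis["codon_index"].to_numpy() - 1, 1)
    return GeneCounts(
        gene_id=transcript.gene_id,
        N=int(len(mis)),
        S=int(len(syn)),
        S_N=int((z > 0).sum()),
        S_S=int(syn["cds_position"].nunique()),
        z=z,
    )


def compute_cncs(
    N: int,
    S: int,
    L_N: float,
    L_S: float,
    zero_s_pseudocount: float = 0.5,
) -> tuple[float, tuple[str, ...]]:
    """C_N/C_S = (N/L_N)/(S/L_S); S=0 substitutes the pseudocount.

    Returns (ratio, flags).  Raises when N+S = 0 (the gene carries no
    information) or when an opportunity count is non-positive.
    """
    if L_N <= 0 or L_S <= 0:
        raise ValueError("L_N and L_S must be positive")
    if N + S == 0:
        raise ValueError("gene has no missense or synonymous mutations")
    flags: tuple[str, ...] = ()
    s_eff = float(S)
    if S == 0:
        s_eff = zero_s_pseudocount
        flags = ("S0_pseudocount",)
    return (N / L_N) / (s_eff / L_S), flags


def compute_H(z: np.ndarray, sample_variance: bool = False) -> float:
    """Among-site heterogeneity of the per-codon missense counts.

    Uses the population variance by default (divisor n).  Returns NaN
    when the gene has no missense mutations (zbar = 0) or fewer than
    two codons; otherwise the raw statistic clamped to [0, 1].
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        return float("nan")
    zbar = z.mean()
    if zbar == 0:
        return float("nan")
    var = z.var(ddof=1 if sample_variance else 0)
    denom = var + zbar * (zbar - 1.0)
    if denom == 0:
        return 0.0
    return float(min(1.0, max(0.0, (var - zbar) / denom)))


def cncs_chisq_test(
    N: int,
    S: int,
    L_N: float,
    L_S: float,
    null_ratio: float = 1.0,
    sided: str = "two-sided",
) -> tuple[float, float, tuple[str, ...]]:
    """Two-cell Pearson goodness-of-fit of (N, S) against a null C_N/C_S.

    Under null ratio rho the expected split of the N+S mutations is
    proportional to (rho*L_N, L_S).  df = 1.  For one-sided tests the
    p-value is halved when the deviation lies in the tested direction
    ("greater": missense excess; "less": missense deficit) and is
    1 - p/2 otherwise.

    Returns (chi2_statistic, p_value, flags); flags warn when an
    expected cell is below 1.
    """
    if null_ratio <= 0:
        raise ValueError("null_ratio must be positive")
    if N + S < 1:
        raise ValueError("need at least one mutation")
    total = N + S
    frac_n = null_ratio * L_N / (null_ratio * L_N + L_S)
    expected = np.array([total * frac_n, total * (1.0 - frac_n)])
    observed = np.array([N, S], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p_two = float(chi2.sf(stat, df=1))
    flags: tuple[str, ...] = ()
    if expected.min() < 1:
        flags = ("small_expected_cell",)
    if sided == "two-sided":
        return stat, p_two, flags
    excess = N > expected[0]
    if sided == "greater":
        p = p_two / 2 if excess else 1.0 - p_two / 2
    elif sided == "less":
        p = p_two / 2 if not excess else 1.0 - p_two / 2
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return stat, float(p), flags


def selection_mode(
    cncs: float,
    H: float,
    p_vs_1: float,
    p_vs_1mH: float,
    alpha_level: float = 0.05,
) -> SelectionMode:
    """Classify the gene-level selection regime.

    dominant_positive: C_N/C_S > 1, significant vs 1.
    weak_positive:     1-H < C_N/C_S < 1, significant vs 1-H (excess).
    negative:          C_N/C_S < 1-H, significant vs 1-H (deficit).
    Everything else is neutral_or_undetermined.
    """
    if np.isfinite(cncs) and cncs > 1 and p_vs_1 < alpha_level:
        return SelectionMode.DOMINANT_POSITIVE
    if np.isfinite(H):
        if 1 - H < cncs < 1 and p_vs_1mH < alpha_level:
            return SelectionMode.WEAK_POSITIVE
        if cncs < 1 - H and p_vs_1mH < alpha_level:
            return SelectionMode.NEGATIVE
    return SelectionMode.NEUTRAL_OR_UNDETERMINED


def gene_selection_stats(
    counts: GeneCounts,
    opportunities: OpportunityCounts,
    alpha_level: float = 0.05,
    zero_s_pseudocount: float = 0.5,
) -> GeneSelectionStats:
    """Full gene-level analysis: C_N/C_S, H, both tests and the mode label."""
    cncs, flags = compute_cncs(
        counts.N, counts.S, opportunities.L_N, opportunities.L_S,
        zero_s_pseudocount=zero_s_pseudocount,
    )
    H = compute_H(counts.z)
    _, _, f1 = cncs_chisq_test(
        counts.N, counts.S, opportunities.L_N, opportunities.L_S, null_ratio=1.0,
        sided="two-sided",
    )
    # directional p for the mode/classification decisions
    _, p_vs1, _ = cncs_chisq_test(
        counts.N, counts.S, opportunities.L_N, opportunities.L_S, null_ratio=1.0,
        sided="greater",
    )
    if np.isfinite(H) and (1 - H) > 0:
        sided = "greater" if cncs >= 1 - H else "less"
        _, p_vs1mH, f2 = cncs_chisq_test(
            counts.N, counts.S, opportunities.L_N, opportunities.L_S,
            null_ratio=1 - H, sided=sided,
        )
    elif np.isfinite(H):  # H == 1: null ratio 0 is degenerate
        p_vs1mH = float("nan")
        f2 = ("H_eq_1",)
    else:
        p_vs1mH = float("nan")
        f2 = ("H_undefined",)
    flags = tuple(dict.fromkeys(flags + f1 + f2))
    mode = selection_mode(cncs, H, p_vs1, p_vs1mH, alpha_level=alpha_level)
    return GeneSelectionStats(
        gene_id=counts.gene_id,
        cncs=cncs,
        H=H,
        p_vs_1=p_vs1,
        p_vs_1mH=p_vs1mH,
        mode=mode,
        flags=flags,
    )
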