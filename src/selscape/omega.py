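"""Driver/passenger decomposition of the gene-level selection ratio.

The overall C_N/C_S of a gene with driver-site fraction eta splits as

    (1 - eta) * Omega_pass + eta * Omega_dri = C_N/C_S

Omega_pass is estimated from the site-occupancy counts,
Omega_pass = (S_N/S_S) / (L_N/L_S), and Omega_dri from the adjusted
count ratio [N/S]* = (N/S - (1 - eta) S_N/S_S) / eta, so that the
identity above holds by construction.  Per-site posterior driver
probabilities Q_k = P(driver | z_k) follow from Bayes' rule on the
mixture, and the site-specific ratio is the posterior mean

    Omega_k = (1 - Q_k) Omega_pass + Q_k [(z_k + alpha)/(m1 + alpha)] Omega_dri
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .mixture import MixtureFit, mixture_pmf, nbd_pmf


@dataclass
class OmegaDecomposition:
    gene_id: str
    omega_pass: float
    omega_dri: float  # NaN when eta = 0
    ns_star: float
    p_pass_lt1: float
    flags: tuple[str, ...] = ()


def omega_pass(
    S_N: int,
    S_S: int,
    L_N: float,
    L_S: float,
    zero_s_pseudocount: float = 0.5,
) -> tuple[float, tuple[str, ...]]:
    """Passenger-component selection ratio (S_N/S_S)/(L_N/L_S)."""
    if S_N + S_S == 0:
        raise ValueError("gene has no mutated sites")
    flags: tuple[str, ...] = ()
    ss_eff = float(S_S)
    if S_S == 0:
        ss_eff = zero_s_pseudocount
        flags = ("SS0_pseudocount",)
    return (S_N / ss_eff) / (L_N / L_S), flags


def omega_dri(
    N: int,
    S: int,
    S_N: int,
    S_S: int,
    eta: float,
    L_N: float,
    L_S: float,
    zero_s_pseudocount: float = 0.5,
) -> tuple[float, float, tuple[str, ...]]:
    """Driver-component selection ratio via the adjusted [N/S]*.

    Returns (ns_star, omega_dri, flags).  Requires eta > 0; a negative
    ns_star (possible at small counts) is floored at 0 with a flag.
    """
    if eta <= 0:
        raise ValueError("omega_dri undefined when eta = 0")
    flags: tuple[str, ...] = ()
    s_eff = float(S)
    if S == 0:
        s_eff = zero_s_pseudocount
        flags += ("S0_pseudocount",)
    ss_eff = float(S_S)
    if S_S == 0:
        ss_eff = zero_s_pseudocount
        flags += ("SS0_pseudocount",)
    ns_star = (N / s_eff - (1.0 - eta) * S_N / ss_eff) / eta
    if ns_star < 0:
        ns_star = 0.0
        flags += ("ns_star_floored",)
    return ns_star, ns_star / (L_N / L_S), flags


def omega_pass_test(
    S_N: int,
    S_S: int,
    L_N: float,
    L_S: float,
) -> tuple[float, float, tuple[str, ...]]:
    """One-sided test for Omega_pass < 1 on the site-occupancy counts.

    Two-cell Pearson goodness-of-fit of (S_N, S_S) against expected
    fractions (L_N, L_S)/(L_N + L_S), df = 1, one-sided toward a
    missense-site deficit; a deviation in the opposite direction reports
    p = 1 - p/2 (never significant).
    """
    if S_N + S_S < 1:
        raise ValueError("need at least one mutated site")
    total = S_N + S_S
    frac_n = L_N / (L_N + L_S)
    expected = np.array([total * frac_n, total * (1 - frac_n)])
    observed = np.array([S_N, S_S], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p_two = float(chi2.sf(stat, df=1))
    flags: tuple[str, ...] = ()
    if expected.min() < 1:
        flags = ("small_expected_cell",)
    deficit = S_N < expected[0]
    p = p_two / 2 if deficit else 1.0 - p_two / 2
    return stat, float(p), flags


def site_posterior(z_k, fit: MixtureFit) -> np.ndarray:
    """Posterior driver probability Q_k = eta * P1(z_k) / f(z_k)."""
    z_k = np.asarray(z_k)
    if fit.eta <= 0 or not np.isfinite(fit.m1):
        return np.zeros(z_k.shape)
    if fit.eta >= 1:
        return np.ones(z_k.shape)
    num = fit.eta * nbd_pmf(z_k, fit.m1, fit.alpha)
    den = mixture_pmf(z_k, fit.m0, fit.m1, fit.eta, fit.alpha)
    return np.asarray(num / den)


def omega_site(z_k, Q_k, fit: MixtureFit, omega_pass: float, omega_dri: float):
    """Site-specific selection ratio by posterior mean shrinkage.

    Omega_k = (1-Q_k) Omega_pass + Q_k [(z_k+alpha)/(m1+alpha)] Omega_dri.
    When the gene has no driver component every site reports Omega_pass.
    """
    z_k = np.asarray(z_k, dtype=float)
    Q_k = np.asarray(Q_k, dtype=float)
    if np.any((Q_k < 0) | (Q_k > 1)):
        raise ValueError("Q_k must lie in [0, 1]")
    if fit.eta <= 0 or not np.isfinite(fit.m1):
        return np.full(z_k.shape, omega_pass)
    shrink = (z_k + fit.alpha) / (fit.m1 + fit.alpha)
    return (1.0 - Q_k) * omega_pass + Q_k * shrink * omega_dri


def decompose_gene(
    gene_id: str,
    N: int,
    S: int,
    S_N: int,
    S_S: int,
    fit: MixtureFit,
    L_N: float,
    L_S: float,
    zero_s_pseudocount: float = 0.5,
) -> OmegaDecomposition:
    """Full decomposition plus the negative-selection test for one gene."""
    o_pass, f1 = omega_pass(S_N, S_S, L_N, L_S, zero_s_pseudocount)
    _, p_lt1, f2 = omega_pass_test(S_N, S_S, L_N, L_S)
    if fit.eta > 0:
        ns_star, o_dri, f3 = omega_dri(
            N, S, S_N, S_S, fit.eta, L_N, L_S, zero_s_pseudocount
        )
    else:
        ns_star, o_dri, f3 = float("nan"), float("nan"), ()
    return OmegaDecomposition(
        gene_id=gene_id,
        omega_pass=o_pass,
        omega_dri=o_dri,
        ns_star=ns_star,
        p_pass_lt1=p_lt1,
        flags=tuple(dict.fromkeys(f1 + f2 + f3)),
    )


def site_table(gene_id: str, z: np.ndarray, fit: MixtureFit,
               o_pass: float, o_dri: float) -> pd.DataFrame:
    """Per-codon posterior table (codon_index, z_k, Q_k, omega_k)."""
    z = np.asarray(z)
    Q = site_posterior(z, fit)
    om = omega_site(z, Q, fit, o_pass, o_dri)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "codon_index": np.arange(1, len(z) + 1),
            "z_k": z,
            "Q_k": Q,
            "omega_k": om,
        }
    )
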