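"""Two-component Poisson-NB mixture over per-codon missense counts.

A gene's codons are either passenger sites, whose missense count is
Poisson with per-site recurrence rate m0, or driver sites (a fraction
eta), whose excess rate lambda is gamma-distributed with shape alpha,
so the driver-site count is approximately negative binomial with mean
m1 and shape alpha:

    f(z) = (1 - eta) Pois(z; m0) + eta NB(z; mean m1, shape alpha)

alpha is treated as a single cohort-wide parameter fitted by maximum
likelihood, profiling (m1, eta) per gene through the moment equations

    zbar        = (1 - eta) m0 + eta m1
    var(z)-zbar = eta (1 - eta) (m1 - m0)^2 + eta m1^2 / alpha

The default (m1, eta) estimator is the closed-form approximation

    m1  = ((var - zbar)/(zbar - m0) + zbar + m0/alpha) / (1 + 1/alpha)
    eta = (zbar - m0) / (m1 - m0)

which assumes m1 >> m0; the exact quadratic inversion of the moment
equations is available as ``mode="exact"``.  The presence of a driver
component (eta > 0) is tested with an approximate likelihood ratio test
against the pure-Poisson model, using the boundary-corrected reference
distribution 0.5*chi2(0) + 0.5*chi2(1) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, nbinom, poisson

logger = logging.getLogger(__name__)

#: cohort-scale maximum-likelihood estimate reported for the gamma shape
#: on the TCGA pan-cancer cohort; used as a fallback when a cohort has no
#: overdispersed gene to fit alpha on.
DEFAULT_ALPHA = 1.51

ALPHA_BOUNDS = (0.05, 100.0)


@dataclass
class MixtureFit:
    """Fitted driver/passenger mixture for one gene."""

    gene_id: str
    m0: float
    m1: float  # NaN when no driver component
    eta: float
    alpha: float
    loglik: float
    lrt_stat: float
    lrt_p: float
    flags: tuple[str, ...] = ()

    @property
    def beta(self) -> float:
        """Implied gamma scale beta = alpha / (m1 - m0); NaN if undefined."""
        if np.isfinite(self.m1) and self.m1 > self.m0:
            return self.alpha / (self.m1 - self.m0)
        return float("nan")


def estimate_m0(
    S: int,
    L_N: float,
    L_S: float,
    n_codons: int,
    cohort_syn_rate: float | None = None,
) -> tuple[float, tuple[str, ...]]:
    """Passenger per-codon missense recurrence rate.

    Default estimator: the gene's synonymous count converted to an
    expected missense count through the opportunity ratio, per codon:
    m0 = S * (L_N/L_S) / n_codons.  When S = 0 the cohort-wide
    synonymous rate per unit of synonymous opportunity (``ΣS / ΣL_S``)
    stands in for the gene's own rate: m0 = cohort_syn_rate * L_N /
    n_codons.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    if L_N <= 0 or L_S <= 0:
        raise ValueError("L_N and L_S must be positive")
    if S > 0:
        return S * (L_N / L_S) / n_codons, ()
    if cohort_syn_rate is None:
        raise ValueError("S=0 and no cohort fallback rate supplied")
    return cohort_syn_rate * L_N / n_codons, ("S0_cohort_fallback",)


def estimate_m0_from_sites(
    z: np.ndarray,
    tail_prob: float = 1e-3,
    max_iter: int = 5,
) -> tuple[float, tuple[str, ...]]:
    """Passenger rate as an outlier-trimmed mean of the per-site counts.

    Recurrently mutated (candidate driver) sites are excluded by
    iteratively trimming sites whose count exceeds the upper
    ``1 - tail_prob`` Poisson quantile of the current estimate, then
    averaging the remainder.  Unlike the synonymous-calibrated
    estimator, this one stays below the gene mean when a minority of
    sites is recurrently hit, which is what lets a weakly selected gene
    (C_N/C_S < 1) still expose its driver component.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty site vector")
    m = float(z.mean())
    if m == 0:
        return 0.0, ("all_sites_zero",)
    flags: tuple[str, ...] = ()
    for _ in range(max_iter):
        threshold = max(poisson.ppf(1.0 - tail_prob, m), 1.0)
        keep = z <= threshold
        m_new = float(z[keep].mean()) if keep.any() else m
        if abs(m_new - m) < 1e-12:
            m = m_new
            break
        m = m_new
    if not keep.all():
        flags = ("recurrent_sites_trimmed",)
    return m, flags


def nbd_pmf(z, m1: float, alpha: float) -> np.ndarray:
    """Negative binomial with mean m1 and shape alpha (variance m1+m1^2/alpha)."""
    return nbinom.pmf(z, alpha, alpha / (m1 + alpha))


def mixture_pmf(z, m0: float, m1: float, eta: float, alpha: float) -> np.ndarray:
    """Mixture probability f(z) of the per-site missense count."""
    z = np.asarray(z)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    pois = poisson.pmf(z, m0)
    if eta == 0:
        return pois
    return (1.0 - eta) * pois + eta * nbd_pmf(z, m1, alpha)


def mixture_loglik(z, m0: float, m1: float, eta: float, alpha: float) -> float:
    p = mixture_pmf(z, m0, m1, eta, alpha)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def mom_estimates(
    z_mean: float,
    z_var: float,
    m0: float,
    alpha: float,
    mode: str = "printed",
) -> tuple[float, float, tuple[str, ...]]:
    """Method-of-moments (m1, eta) at a given m0 and alpha.

    ``mode="printed"`` uses the closed-form approximation; ``"exact"``
    solves the quadratic moment inversion.  When z_mean <= m0 there is
    no driver signal and (NaN, 0.0) is returned.  eta is truncated to
    [0, 1] with a flag.
    """
    if z_var < 0:
        raise ValueError("variance cannot be negative")
    if z_mean <= m0:
        return float("nan"), 0.0, ()
    flags: tuple[str, ...] = ()
    excess = z_mean - m0
    if mode == "printed":
        m1 = (
            (z_var - z_mean) / excess + z_mean + m0 / alpha
        ) / (1.0 + 1.0 / alpha)
    elif mode == "exact":
        m1 = _exact_m1(z_mean, z_var, m0, alpha)
        if not np.isfinite(m1):
            flags += ("exact_inversion_failed",)
            m1 = (
                (z_var - z_mean) / excess + z_mean + m0 / alpha
            ) / (1.0 + 1.0 / alpha)
    else:
        raise ValueError(f"unknown moment mode {mode!r}")
    if m1 <= m0:
        # approximation can land at or below m0 under weak overdispersion
        flags += ("m1_le_m0",)
        return float("nan"), 0.0, flags
    eta = excess / (m1 - m0)
    if eta > 1.0:
        eta = 1.0
        flags += ("eta_truncated",)
    return float(m1), float(eta), flags


def _exact_m1(z_mean: float, z_var: float, m0: float, alpha: float) -> float:
    """Exact quadratic inversion of the moment equations for d = m1 - m0.

    Substituting eta = (zbar - m0)/d into the second moment equation
    gives e(1+1/a) d^2 + (2 e m0/a - e^2 - v) d + e m0^2/a = 0 with
    e = zbar - m0 and v = var - zbar.  The admissible root has d >= e
    (so that eta <= 1); the larger such root is the driver-regime
    solution.
    """
    e = z_mean - m0
    v = z_var - z_mean
    A = e * (1.0 + 1.0 / alpha)
    B = 2.0 * e * m0 / alpha - e * e - v
    C = e * m0 * m0 / alpha
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return float("nan")
    roots = np.array([(-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A)])
    admissible = roots[(roots > 0) & (roots >= e * (1 - 1e-12))]
    if admissible.size == 0:
        positive = roots[roots > 0]
        if positive.size == 0:
            return float("nan")
        return float(positive.max() + m0)
    return float(admissible.max() + m0)


def fit_alpha_global(
    z_vectors: list[np.ndarray],
    m0_values: list[float],
    mom_mode: str = "printed",
    bounds: tuple[float, float] = ALPHA_BOUNDS,
) -> tuple[float, tuple[str, ...]]:
    """Cohort-wide gamma shape by profile maximum likelihood.

    For each candidate alpha, (m1, eta) of every eligible gene (those
    with zbar > m0 and var(z) > zbar) are profiled through the moment
    equations and the summed mixture log-likelihood is evaluated; the
    alpha maximising the sum is returned.  With no overdispersed gene
    the published cohort-scale value 1.51 is returned with a warning
    flag.
    """
    eligible = []
    for z, m0 in zip(z_vectors, m0_values):
        z = np.asarray(z, dtype=float)
        if z.size >= 2 and z.mean() > m0 and z.var() > z.mean():
            eligible.append((z, m0))
    if not eligible:
        logger.warning(
            "no gene with excess variance; falling back to alpha = %.2f",
            DEFAULT_ALPHA,
        )
        return DEFAULT_ALPHA, ("alpha_fallback",)

    moments = [(z, float(z.mean()), float(z.var()), m0) for z, m0 in eligible]

    def neg_loglik(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        total = 0.0
        for z, mean, var, m0 in moments:
            m1, eta, _ = mom_estimates(mean, var, m0, a, mode=mom_mode)
            if eta <= 0 or not np.isfinite(m1):
                total += float(np.sum(poisson.logpmf(z, m0)))
            else:
                total += mixture_loglik(z, m0, m1, eta, a)
        return -total

    res = minimize_scalar(
        neg_loglik,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(res.x))
    flags: tuple[str, ...] = ()
    if alpha <= bounds[0] * 1.05 or alpha >= bounds[1] * 0.95:
        flags = ("alpha_boundary",)
    return alpha, flags


def lrt_eta(
    z: np.ndarray,
    m0: float,
    m1: float,
    eta: float,
    alpha: float,
    df_mode: str = "half1",
) -> tuple[float, float]:
    """Approximate LRT for eta > 0 against the pure-Poisson model.

    Lambda = 2 [loglik(mixture at the moment estimates) - loglik(Pois(m0))],
    clamped at 0 (the moment estimates are not exact MLEs).  The p-value
    uses the boundary mixture 0.5*chi2(0) + 0.5*chi2(1) (``"half1"``) or
    chi2 with 2 df (``"chi2_2"``).
    """
    z = np.asarray(z, dtype=float)
    ll_null = float(np.sum(poisson.logpmf(z, m0)))
    if eta <= 0 or not np.isfinite(m1):
        return 0.0, 1.0
    stat = 2.0 * (mixture_loglik(z, m0, m1, eta, alpha) - ll_null)
    stat = max(0.0, float(stat))
    if stat == 0.0:
        return 0.0, 1.0
    if df_mode == "half1":
        p = 0.5 * float(chi2.sf(stat, df=1))
    elif df_mode == "chi2_2":
        p = float(chi2.sf(stat, df=2))
    else:
        raise ValueError(f"unknown LRT df mode {df_mode!r}")
    return stat, p


def fit_gene_mixture(
    gene_id: str,
    z: np.ndarray,
    m0: float,
    alpha: float,
    m0_flags: tuple[str, ...] = (),
    mom_mode: str = "printed",
    lrt_df_mode: str = "half1",
) -> MixtureFit:
    """Moment fit plus LRT for one gene at a fixed global alpha."""
    z = np.asarray(z, dtype=float)
    mean, var = float(z.mean()), float(z.var())
    m1, eta, flags = mom_estimates(mean, var, m0, alpha, mode=mom_mode)
    stat, p = lrt_eta(z, m0, m1, eta, alpha, df_mode=lrt_df_mode)
    if eta > 0 and np.isfinite(m1):
        ll = mixture_loglik(z, m0, m1, eta, alpha)
    else:
        ll = float(np.sum(poisson.logpmf(z, m0)))
    return MixtureFit(
        gene_id=gene_id,
        m0=m0,
        m1=m1,
        eta=eta,
        alpha=alpha,
        loglik=ll,
        lrt_stat=stat,
        lrt_p=p,
        flags=tuple(dict.fromkeys(m0_flags + flags)),
    )
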