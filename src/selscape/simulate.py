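"""Synthetic somatic-mutation cohorts with known ground truth.

The generator realises the same generative model the inference assumes:
each codon of a random sense-codon CDS is independently a driver site
with probability eta; passenger codons accumulate missense mutations as
Poisson(m0), driver codons as Poisson(m0 + lambda) with lambda drawn
from a Gamma(alpha, beta) with mean m1 - m0.  Synonymous mutations are
placed with intensity m0 * n_codons * L_S/L_N, so a fully neutral gene
has E[C_N/C_S] = 1 by construction, and individual events are assigned
to substitutions in proportion to the context-spectrum rates.  An
optional conserved fraction of passenger codons produces no missense
mutations at all, emulating sites under strong negative selection.

Output is the same MAF dialect and CDS FASTA the ingest layer reads,
plus ground-truth tables, so the whole pipeline is testable without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import MISSENSE, SENSE_CODONS, STOP_CODONS, SYNONYMOUS
from .io import CodingTranscript
from .spectrum import ContextSpectrum, _coding_change_arrays

_ALT_OF = {i: [b for b in range(4) if b != i] for i in range(4)}
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated gene group."""

    n_genes: int
    n_codons: int | tuple[int, int]  # fixed length or inclusive range
    eta: float
    m0: float
    m1: float
    alpha: float = 1.51
    conserved_fraction: float = 0.0  # passenger codons with no missense
    spectrum: ContextSpectrum | str = "uniform"
    n_samples: int = 100
    seed: int | None = None
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must lie in [0, 1]")
        if self.m0 < 0 or self.alpha <= 0:
            raise ValueError("rates must be non-negative and alpha positive")
        if self.eta > 0 and self.m1 <= self.m0:
            raise ValueError("m1 must exceed m0 when eta > 0")
        if not 0 <= self.conserved_fraction < 1:
            raise ValueError("conserved_fraction must lie in [0, 1)")

    def resolved_spectrum(self) -> ContextSpectrum:
        if isinstance(self.spectrum, str):
            if self.spectrum != "uniform":
                raise ValueError(f"unknown spectrum preset {self.spectrum!r}")
            return ContextSpectrum.uniform()
        return self.spectrum.normalized()


@dataclass
class SimulatedCohort:
    """In-memory fixture: MAF-style table, transcripts and ground truth."""

    maf: pd.DataFrame
    transcripts: dict
    truth_genes: pd.DataFrame
    truth_sites: pd.DataFrame

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": out_dir / "cohort.maf.tsv",
            "fasta": out_dir / "cds.fasta",
            "truth_genes": out_dir / "truth_genes.tsv",
            "truth_sites": out_dir / "truth_sites.tsv",
        }
        self.maf.to_csv(paths["maf"], sep="\t", index=False)
        with open(paths["fasta"], "w") as fh:
            for gene_id in sorted(self.transcripts):
                tx = self.transcripts[gene_id]
                fh.write(f">{gene_id}|{tx.transcript_id}\n{tx.cds_sequence}\n")
        self.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        return paths


def simulate_site_counts(
    rng: np.random.Generator,
    n_sites: int,
    eta: float,
    m0: float,
    m1: float,
    alpha: float,
    conserved_fraction: float = 0.0,
) -> dict:
    """Draw one gene's per-codon missense counts from the mixture.

    Returns z, the per-site driver indicator, per-site lambda (0 at
    passenger sites) and the realised per-site Poisson rates.  This is
    the fast count-level path used for calibration studies; the full
    cohort generator routes every count through real sequences.
    """
    driver = rng.random(n_sites) < eta
    lam = np.zeros(n_sites)
    n_driver = int(driver.sum())
    if n_driver and m1 > m0:
        lam[driver] = rng.gamma(alpha, (m1 - m0) / alpha, size=n_driver)
    rates = np.where(driver, m0 + lam, m0)
    if conserved_fraction > 0:
        conserved = (~driver) & (rng.random(n_sites) < conserved_fraction)
        rates = np.where(conserved, 0.0, rates)
    else:
        conserved = np.zeros(n_sites, dtype=bool)
    z = rng.poisson(rates)
    return {"z": z, "driver": driver, "lam": lam, "rates": rates,
            "conserved": conserved}


def analytic_H(
    eta: float,
    m0: float,
    m1: float,
    alpha: float,
    conserved_fraction: float = 0.0,
) -> float:
    """H = 1 - (E[r])^2 / E[r^2] of the generating per-site rate law."""
    c = conserved_fraction
    mu = m1 - m0  # mean gamma excess
    e_r = (1 - eta) * (1 - c) * m0 + eta * m1
    e_driver_sq = m0**2 + 2 * m0 * mu + mu**2 * (1 + 1 / alpha)
    e_r2 = (1 - eta) * (1 - c) * m0**2 + eta * e_driver_sq
    if e_r2 == 0:
        return 0.0
    return 1.0 - e_r**2 / e_r2


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
    return "".join(codons) + stop


def _weighted_choice(rng, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0:
        return int(rng.integers(len(weights)))
    return int(rng.choice(len(weights), p=weights / total))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (sequences + MAF + ground truth)."""
    if config.seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    rng = np.random.default_rng(config.seed)
    spectrum = config.resolved_spectrum()

    maf_rows: list[tuple] = []
    gene_rows: list[dict] = []
    site_frames: list[pd.DataFrame] = []
    transcripts: dict[str, CodingTranscript] = {}
    samples = [f"SAMPLE_{i:04d}" for i in range(config.n_samples)]

    for g in range(config.n_genes):
        gene_id = f"{config.gene_prefix}{g:04d}"
        transcript_id = f"{gene_id}.t1"
        if isinstance(config.n_codons, tuple):
            lo, hi = config.n_codons
            n_codons = int(rng.integers(lo, hi + 1))
        else:
            n_codons = int(config.n_codons)
        cds = _random_cds(rng, n_codons)
        tx = CodingTranscript(gene_id, transcript_id, cds)
        transcripts[gene_id] = tx

        cons, ctx = _coding_change_arrays(cds, n_codons)
        rates = np.where(ctx >= 0, spectrum.rates[np.clip(ctx, 0, None)], 1.0)
        mis_rates = np.where(cons == MISSENSE, rates, 0.0)  # (3n, 3)
        syn_rates = np.where(cons == SYNONYMOUS, rates, 0.0)
        L_N = float(mis_rates.sum())
        L_S = float(syn_rates.sum())

        sim = simulate_site_counts(
            rng, n_codons, config.eta, config.m0, config.m1, config.alpha,
            config.conserved_fraction,
        )
        z = sim["z"]

        # place missense events inside their codon, weighted by context rate
        for k in np.flatnonzero(z):
            w = mis_rates[3 * k : 3 * k + 3].ravel()
            for _ in range(int(z[k])):
                pick = _weighted_choice(rng, w)
                pos_in_codon, alt_slot = divmod(pick, 3)
                p = 3 * k + pos_in_codon  # 0-based CDS position
                ref = cds[p]
                alt = _BASES[_ALT_OF["ACGT".index(ref)][alt_slot]]
                maf_rows.append(
                    (samples[rng.integers(len(samples))], gene_id, transcript_id,
                     "Missense_Mutation", p + 1, ref, alt)
                )

        # synonymous events at the neutral intensity implied by m0
        syn_flat = syn_rates.ravel()
        if L_S > 0:
            n_syn = rng.poisson(config.m0 * n_codons * L_S / L_N)
            for _ in range(int(n_syn)):
                pick = _weighted_choice(rng, syn_flat)
                p, alt_slot = divmod(pick, 3)
                ref = cds[p]
                alt = _BASES[_ALT_OF["ACGT".index(ref)][alt_slot]]
                maf_rows.append(
                    (samples[rng.integers(len(samples))], gene_id, transcript_id,
                     "Silent", p + 1, ref, alt)
                )

        gene_rows.append(
            {
                "gene_id": gene_id,
                "n_codons": n_codons,
                "eta": config.eta,
                "m0": config.m0,
                "m1": config.m1,
                "alpha": config.alpha,
                "conserved_fraction": config.conserved_fraction,
                "n_driver_sites": int(sim["driver"].sum()),
                "L_N": L_N,
                "L_S": L_S,
            }
        )
        site_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "codon_index": np.arange(1, n_codons + 1),
                    "is_driver": sim["driver"].astype(int),
                    "is_conserved": sim["conserved"].astype(int),
                    "lam": sim["lam"],
                    "z_true": z,
                }
            )
        )

    maf = pd.DataFrame(
        maf_rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Transcript_ID",
            "Variant_Classification",
            "CDS_position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
        ],
    )
    truth_sites = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else pd.DataFrame()
    )
    return SimulatedCohort(
        maf=maf,
        transcripts=transcripts,
        truth_genes=pd.DataFrame(gene_rows),
        truth_sites=truth_sites,
    )


def simulate_groups(
    configs: list[SimulationConfig], seed: int
) -> SimulatedCohort:
    """Simulate several gene groups into one cohort sharing a sample pool.

    Each group gets a seed derived from ``seed`` and must carry a
    distinct gene_prefix.
    """
    prefixes = [c.gene_prefix for c in configs]
    if len(set(prefixes)) != len(prefixes):
        raise ValueError("gene prefixes of simulation groups must be distinct")
    parts = [
        simulate_cohort(replace(c, seed=seed + 1000 * i))
        for i, c in enumerate(configs)
    ]
    transcripts: dict = {}
    for p in parts:
        transcripts.update(p.transcripts)
    return SimulatedCohort(
        maf=pd.concat([p.maf for p in parts], ignore_index=True),
        transcripts=transcripts,
        truth_genes=pd.concat([p.truth_genes for p in parts], ignore_index=True),
        truth_sites=pd.concat([p.truth_sites for p in parts], ignore_index=True),
    )


def recovery_report(
    truth_genes: pd.DataFrame, estimates: pd.DataFrame
) -> pd.DataFrame:
    """Per-parameter recovery metrics of pipeline estimates vs ground truth.

    Joins on gene_id and reports, for each parameter present in both
    tables (eta, m1, m0), the median estimate, true value, bias, RMSE
    and median relative error.  Raises when the gene sets disagree.
    """
    t = truth_genes.set_index("gene_id")
    e = estimates.set_index("gene_id")
    missing = t.index.difference(e.index)
    if len(missing):
        raise ValueError(f"estimates missing for {len(missing)} genes")
    e = e.loc[t.index]
    rows = []
    for param in ("eta", "m1", "m0"):
        if param not in t.columns or param not in e.columns:
            continue
        true = t[param].to_numpy(dtype=float)
        est = e[param].to_numpy(dtype=float)
        ok = np.isfinite(est) & np.isfinite(true)
        true, est = true[ok], est[ok]
        if len(true) == 0:
            continue
        err = est - true
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(true != 0, err / true, np.nan)
        rows.append(
            {
                "parameter": param,
                "n_genes": len(true),
                "true_median": float(np.median(true)),
                "estimate_median": float(np.median(est)),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "median_relative_error": float(np.nanmedian(rel)),
            }
        )
    return pd.DataFrame(rows)
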