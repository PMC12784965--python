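"""Model/results objects tying the analysis layers together.

``SelectionModel`` holds an annotated cohort and the selected coding
transcripts; ``fit()`` runs spectrum estimation, gene-level C_N/C_S-H
statistics, the driver/passenger mixture on genes passing the
positive-selection gate (C_N/C_S > 1-H), the omega decomposition and
the final classification, returning a ``SelectionResults`` with tidy
per-gene tables and a text ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classify as _classify
from . import gene_selection as _gs
from . import mixture as _mix
from . import omega as _om
from .io import (
    CohortDataset,
    annotate_cohort,
    filter_hypermutators,
    read_cds_fasta,
    read_maf,
)
from .spectrum import ContextSpectrum, estimate_context_rates, expected_sites

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline options; defaults reproduce the published analysis choices."""

    alpha_level: float = 0.05
    zero_s_pseudocount: float = 0.5
    spectrum_pseudocount: float = 0.5
    m0_method: str = "sites_trimmed"  # sites_trimmed | synonymous
    mom_mode: str = "printed"  # printed | exact
    lrt_df_mode: str = "half1"  # half1 | chi2_2
    minidriver_rule: str = "joint"  # joint | band_only
    dubious_filter: bool = True
    dubious_genes: tuple[str, ...] | None = None  # None -> default six
    hypermutator_filter: bool = True
    use_context_spectrum: bool = True
    fixed_alpha: float | None = None  # skip the global alpha fit
    seed: int = 0

    def as_manifest(self) -> dict:
        d = asdict(self)
        d["dubious_genes"] = (
            ",".join(self.dubious_genes) if self.dubious_genes else "default"
        )
        return d


class SelectionModel:
    """Site-component selection-pressure model of a somatic-mutation cohort."""

    def __init__(
        self,
        cohort: CohortDataset,
        transcripts: dict,
        config: RunConfig | None = None,
    ):
        self.cohort = cohort
        self.transcripts = transcripts
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        maf_path,
        cds_fasta_path,
        cancer_types_path=None,
        transcript_table_path=None,
        config: RunConfig | None = None,
        column_map: dict | None = None,
    ) -> "SelectionModel":
        """Build the model straight from MAF + FASTA (+ optional tables)."""
        config = config or RunConfig()
        transcript_table = None
        if transcript_table_path is not None:
            tt = pd.read_csv(transcript_table_path, sep="\t")
            transcript_table = dict(zip(tt["gene_id"], tt["transcript_id"]))
        transcripts = read_cds_fasta(cds_fasta_path, transcript_table)
        raw = read_maf(maf_path, column_map)
        cancer_types = None
        if cancer_types_path is not None:
            cancer_types = pd.read_csv(cancer_types_path, sep="\t")[
                ["sample_id", "cancer_type"]
            ]
        cohort = annotate_cohort(raw, transcripts, cancer_types)
        if config.hypermutator_filter:
            cohort = filter_hypermutators(cohort)
        return cls(cohort, transcripts, config)

    @classmethod
    def from_simulated(cls, sim, config: RunConfig | None = None) -> "SelectionModel":
        """Build from an in-memory ``SimulatedCohort`` without file I/O."""
        raw = sim.maf.rename(
            columns={
                "Tumor_Sample_Barcode": "sample_id",
                "Hugo_Symbol": "gene_id",
                "Transcript_ID": "transcript_id",
                "Reference_Allele": "ref_base",
                "Tumor_Seq_Allele2": "alt_base",
                "Variant_Classification": "variant_class",
                "CDS_position": "cds_position",
            }
        )
        raw["cds_position"] = raw["cds_position"].astype("Int64")
        raw["consequence"] = (
            raw["variant_class"].map({"Silent": "synonymous",
                                      "Missense_Mutation": "missense"})
            .fillna("other")
        )
        cohort = annotate_cohort(raw, sim.transcripts)
        config = config or RunConfig()
        if config.hypermutator_filter:
            cohort = filter_hypermutators(cohort)
        return cls(cohort, sim.transcripts, config)

    # ------------------------------------------------------------------
    def fit(self) -> "SelectionResults":
        cfg = self.config
        records = self.cohort.records
        genes = sorted(set(records["gene_id"]) & set(self.transcripts))

        by_gene = {g: df for g, df in records.groupby("gene_id")}

        # 1. context spectrum from cohort synonymous mutations
        syn = records[records["consequence"] == "synonymous"]
        if cfg.use_context_spectrum and syn["context_class"].notna().any():
            spectrum = estimate_context_rates(
                syn,
                list(self.transcripts.values()),
                pseudocount=cfg.spectrum_pseudocount,
            )
        else:
            if cfg.use_context_spectrum:
                logger.warning(
                    "no synonymous mutation with context; using uniform spectrum"
                )
            spectrum = ContextSpectrum.uniform()

        # 2. opportunities and tallies
        opportunities = {
            g: expected_sites(self.transcripts[g], spectrum) for g in genes
        }
        tallies = {
            g: _gs.tally_gene(by_gene[g], self.transcripts[g]) for g in genes
        }

        total_S = sum(t.S for t in tallies.values())
        total_LS = sum(opportunities[g].L_S for g in genes)
        cohort_syn_rate = total_S / total_LS if total_LS > 0 else 0.0

        # 3. gene-level selection statistics
        stats: dict[str, _gs.GeneSelectionStats] = {}
        skipped: list[str] = []
        for g in genes:
            t = tallies[g]
            if t.N + t.S == 0:
                skipped.append(g)
                continue
            stats[g] = _gs.gene_selection_stats(
                t,
                opportunities[g],
                alpha_level=cfg.alpha_level,
                zero_s_pseudocount=cfg.zero_s_pseudocount,
            )

        # 4. positive-selection gate and global alpha
        gated = [
            g
            for g, s in stats.items()
            if np.isfinite(s.H) and s.cncs > 1 - s.H
        ]
        m0_by_gene: dict[str, tuple[float, tuple[str, ...]]] = {}
        for g in gated:
            t, opp = tallies[g], opportunities[g]
            if cfg.m0_method == "sites_trimmed":
                m0_by_gene[g] = _mix.estimate_m0_from_sites(t.z)
            elif cfg.m0_method == "synonymous":
                m0_by_gene[g] = _mix.estimate_m0(
                    t.S, opp.L_N, opp.L_S, t.n_codons, cohort_syn_rate
                )
            else:
                raise ValueError(f"unknown m0 method {cfg.m0_method!r}")
        if cfg.fixed_alpha is not None:
            alpha, alpha_flags = float(cfg.fixed_alpha), ("alpha_fixed",)
        elif gated:
            alpha, alpha_flags = _mix.fit_alpha_global(
                [tallies[g].z for g in gated],
                [m0_by_gene[g][0] for g in gated],
                mom_mode=cfg.mom_mode,
            )
        else:
            alpha, alpha_flags = _mix.DEFAULT_ALPHA, ("alpha_fallback",)

        # 5. per-gene mixture fits and omega decomposition
        fits: dict[str, _mix.MixtureFit] = {}
        omegas: dict[str, _om.OmegaDecomposition] = {}
        for g in gated:
            t, opp = tallies[g], opportunities[g]
            m0, m0_flags = m0_by_gene[g]
            fit = _mix.fit_gene_mixture(
                g,
                t.z,
                m0,
                alpha,
                m0_flags=m0_flags,
                mom_mode=cfg.mom_mode,
                lrt_df_mode=cfg.lrt_df_mode,
            )
            fits[g] = fit
            omegas[g] = _om.decompose_gene(
                g, t.N, t.S, t.S_N, t.S_S, fit, opp.L_N, opp.L_S,
                zero_s_pseudocount=cfg.zero_s_pseudocount,
            )

        # 6. classification
        classifications = [
            _classify.classify_gene(
                stats[g],
                fits.get(g),
                omegas.get(g),
                alpha_level=cfg.alpha_level,
                minidriver_rule=cfg.minidriver_rule,
            )
            for g in sorted(stats)
        ]
        if cfg.dubious_filter:
            classifications = _classify.filter_dubious(
                classifications, cfg.dubious_genes
            )
        _classify.check_label_invariants(classifications)

        return SelectionResults(
            model=self,
            spectrum=spectrum,
            alpha=alpha,
            alpha_flags=alpha_flags,
            tallies=tallies,
            opportunities=opportunities,
            stats=stats,
            fits=fits,
            omegas=omegas,
            classifications=classifications,
            skipped_genes=skipped,
            cohort_syn_rate=cohort_syn_rate,
        )


@dataclass
class SelectionResults:
    """Fitted selection landscape of a cohort."""

    model: SelectionModel
    spectrum: ContextSpectrum
    alpha: float
    alpha_flags: tuple[str, ...]
    tallies: dict
    opportunities: dict
    stats: dict
    fits: dict
    omegas: dict
    classifications: list
    skipped_genes: list[str]
    cohort_syn_rate: float
    _gene_stats: pd.DataFrame | None = field(default=None, repr=False)

    # ------------------------------------------------------------------
    @property
    def gene_stats(self) -> pd.DataFrame:
        """Per-gene table: counts, opportunities, C_N/C_S, H, tests, mode."""
        if self._gene_stats is None:
            rows = []
            for g in sorted(self.stats):
                t, opp, s = self.tallies[g], self.opportunities[g], self.stats[g]
                fit = self.fits.get(g)
                om = self.omegas.get(g)
                rows.append(
                    {
                        "gene_id": g,
                        "N": t.N,
                        "S": t.S,
                        "S_N": t.S_N,
                        "S_S": t.S_S,
                        "n_codons": t.n_codons,
                        "L_N": opp.L_N,
                        "L_S": opp.L_S,
                        "cncs": s.cncs,
                        "H": s.H,
                        "p_vs_1": s.p_vs_1,
                        "p_vs_1mH": s.p_vs_1mH,
                        "mode": s.mode.value,
                        "m0": fit.m0 if fit else np.nan,
                        "m1": fit.m1 if fit else np.nan,
                        "eta": fit.eta if fit else np.nan,
                        "lrt_stat": fit.lrt_stat if fit else np.nan,
                        "lrt_p": fit.lrt_p if fit else np.nan,
                        "omega_pass": om.omega_pass if om else np.nan,
                        "omega_dri": om.omega_dri if om else np.nan,
                        "ns_star": om.ns_star if om else np.nan,
                        "p_pass_lt1": om.p_pass_lt1 if om else np.nan,
                        "flags": ";".join(
                            dict.fromkeys(
                                s.flags
                                + (fit.flags if fit else ())
                                + (om.flags if om else ())
                            )
                        ),
                    }
                )
            self._gene_stats = pd.DataFrame(rows)
        return self._gene_stats

    @property
    def classifications_frame(self) -> pd.DataFrame:
        return _classify.classifications_frame(self.classifications)

    def site_posteriors(self, gene_id: str) -> pd.DataFrame:
        """Per-codon Q_k and omega_k table for one fitted gene."""
        if gene_id not in self.fits:
            raise KeyError(f"{gene_id} has no mixture fit (failed the gate)")
        fit = self.fits[gene_id]
        om = self.omegas[gene_id]
        return _om.site_table(
            gene_id, self.tallies[gene_id].z, fit, om.omega_pass, om.omega_dri
        )

    def label_counts(self) -> dict[str, int]:
        df = self.classifications_frame
        counts = {label: 0 for label in _classify.LABELS}
        for label, n in df["label"].value_counts().items():
            counts[label] = int(n)
        return counts

    # ------------------------------------------------------------------
    def summary(self) -> str:
        df = self.gene_stats
        counts = self.label_counts()
        finite = df["cncs"].replace([np.inf, -np.inf], np.nan).dropna()
        lines = [
            "Selection landscape summary",
            "=" * 45,
            f"genes analysed            {len(df):>10d}",
            f"genes skipped (no data)   {len(self.skipped_genes):>10d}",
            f"mean C_N/C_S              {finite.mean():>10.3f}",
            f"global gamma shape alpha  {self.alpha:>10.3f}"
            + (f"  [{', '.join(self.alpha_flags)}]" if self.alpha_flags else ""),
            f"genes past mixture gate   {len(self.fits):>10d}",
            "-" * 45,
        ]
        for label in _classify.LABELS:
            lines.append(f"{label:<25s} {counts[label]:>10d}")
        eta_pos = df.loc[df["eta"] > 0, "eta"]
        if len(eta_pos):
            lines.append("-" * 45)
            lines.append(f"mean eta (eta > 0)        {eta_pos.mean():>10.4f}")
            od = df.loc[df["eta"] > 0, "omega_dri"].dropna()
            op = df["omega_pass"].dropna()
            if len(od):
                lines.append(f"mean omega_dri            {od.mean():>10.3f}")
            if len(op):
                lines.append(f"mean omega_pass           {op.mean():>10.3f}")
        return "\n".join(lines)

    def plot_landscape(self, path=None):
        """Volcano-style view of the selection landscape.

        Left: log10 C_N/C_S against -log10 p (vs the neutral ratio 1).
        Right: C_N/C_S - (1-H) against -log10 p (vs the 1-H null), the
        plane in which weak positive selection becomes visible.
        Returns the matplotlib figure; saves it when ``path`` is given.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.gene_stats
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        with np.errstate(divide="ignore"):
            x1 = np.log10(df["cncs"].clip(lower=1e-3))
            y1 = -np.log10(df["p_vs_1"].clip(lower=1e-300))
            x2 = df["cncs"] - (1 - df["H"])
            y2 = -np.log10(df["p_vs_1mH"].clip(lower=1e-300))
        ax1.scatter(x1, y1, s=6, alpha=0.5, linewidths=0)
        ax1.axvline(0, color="grey", lw=0.8)
        ax1.set_xlabel("log10 C_N/C_S")
        ax1.set_ylabel("-log10 p (vs 1)")
        ax2.scatter(x2, y2, s=6, alpha=0.5, linewidths=0)
        ax2.axvline(0, color="grey", lw=0.8)
        ax2.set_xlabel("C_N/C_S - (1-H)")
        ax2.set_ylabel("-log10 p (vs 1-H)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig

    def save(self, out_dir, manifest_extra: dict | None = None) -> dict:
        """Write all result tables, spectrum and manifest to a directory."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.gene_stats.to_csv(
            out_dir / "gene_stats.tsv", sep="\t", index=False, float_format="%.6g"
        )
        self.spectrum.to_tsv(out_dir / "spectrum.tsv")
        # per-site tables only for genes with a driver component
        site_frames = [
            self.site_posteriors(g)
            for g in sorted(self.fits)
            if self.fits[g].eta > 0
        ]
        sites = (
            pd.concat(site_frames, ignore_index=True)
            if site_frames
            else pd.DataFrame(
                columns=["gene_id", "codon_index", "z_k", "Q_k", "omega_k"]
            )
        )
        sites.to_csv(
            out_dir / "site_posteriors.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        manifest = self.model.config.as_manifest()
        manifest["alpha_global"] = f"{self.alpha:.6g}"
        manifest["alpha_flags"] = ",".join(self.alpha_flags) or "none"
        manifest.update(manifest_extra or {})
        paths = _classify.write_results(self.classifications, out_dir, manifest)
        paths["gene_stats"] = out_dir / "gene_stats.tsv"
        paths["spectrum"] = out_dir / "spectrum.tsv"
        paths["site_posteriors"] = out_dir / "site_posteriors.tsv"
        return paths
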