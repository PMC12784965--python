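"""Final gene classification: drivers, mini-drivers, conserved mini-drivers.

driver:                 C_N/C_S > 1 significant AND a significant driver
                        component (eta > 0, LRT).
mini_driver:            1-H < C_N/C_S < 1 significant AND a significant
                        driver component (the "joint" rule; the
                        "band_only" rule drops the LRT requirement).
conserved_mini_driver:  mini_driver AND Omega_pass significantly < 1.

A configurable dubious-gene filter removes genes that are recurrent
false positives of mutation-based driver detection.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_selection import GeneSelectionStats
from .mixture import MixtureFit
from .omega import OmegaDecomposition

#: recurrent false-positive genes removed by default by the dubious filter
DEFAULT_DUBIOUS_GENES = ("TTN", "FLG", "PCLO", "CSMD3", "CNTN5", "LRP1B")

LABELS = ("driver", "mini_driver", "conserved_mini_driver", "unclassified")


@dataclass
class GeneClassification:
    gene_id: str
    label: str
    cncs: float = float("nan")
    H: float = float("nan")
    p_vs_1: float = float("nan")
    p_vs_1mH: float = float("nan")
    eta: float = float("nan")
    lrt_p: float = float("nan")
    omega_pass: float = float("nan")
    omega_dri: float = float("nan")
    p_pass_lt1: float = float("nan")
    dubious_filtered: bool = False
    reason: str = ""


def classify_gene(
    stats: GeneSelectionStats,
    fit: MixtureFit | None,
    omega: OmegaDecomposition | None,
    alpha_level: float = 0.05,
    minidriver_rule: str = "joint",
) -> GeneClassification:
    """Apply the three-way decision rules to one gene's analysis layers."""
    base = GeneClassification(
        gene_id=stats.gene_id,
        label="unclassified",
        cncs=stats.cncs,
        H=stats.H,
        p_vs_1=stats.p_vs_1,
        p_vs_1mH=stats.p_vs_1mH,
    )
    if fit is not None:
        base = replace(base, eta=fit.eta, lrt_p=fit.lrt_p)
    if omega is not None:
        base = replace(
            base,
            omega_pass=omega.omega_pass,
            omega_dri=omega.omega_dri,
            p_pass_lt1=omega.p_pass_lt1,
        )

    gene_positive = stats.cncs > 1 and stats.p_vs_1 < alpha_level
    weak_positive = (
        np.isfinite(stats.H)
        and (1 - stats.H) < stats.cncs < 1
        and stats.p_vs_1mH < alpha_level
    )
    if not (gene_positive or weak_positive):
        return replace(base, reason="no gene-level positive selection signal")
    if fit is None:
        return replace(base, reason="mixture layer not computed")
    has_driver_sites = fit.eta > 0 and fit.lrt_p < alpha_level

    if gene_positive:
        if has_driver_sites:
            return replace(base, label="driver")
        return replace(base, reason="no significant driver component")

    # weak positive band
    if minidriver_rule == "joint":
        if not has_driver_sites:
            return replace(base, reason="no significant driver component")
    elif minidriver_rule == "band_only":
        pass
    else:
        raise ValueError(f"unknown mini-driver rule {minidriver_rule!r}")
    label = "mini_driver"
    if (
        omega is not None
        and omega.omega_pass < 1
        and omega.p_pass_lt1 < alpha_level
    ):
        label = "conserved_mini_driver"
    return replace(base, label=label)


def filter_dubious(
    classifications: list[GeneClassification],
    gene_list: tuple[str, ...] | None = None,
) -> list[GeneClassification]:
    """Mark genes on the dubious list; an empty tuple disables the filter."""
    genes = DEFAULT_DUBIOUS_GENES if gene_list is None else tuple(gene_list)
    return [
        replace(c, dubious_filtered=c.gene_id in genes) for c in classifications
    ]


def classifications_frame(classifications: list[GeneClassification]) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in classifications])
    if len(df) == 0:
        df = pd.DataFrame(columns=list(GeneClassification("", "").__dict__))
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def check_label_invariants(classifications: list[GeneClassification]) -> None:
    """Each gene carries exactly one valid label; conserved mini-drivers
    must show the passenger-conservation signal they were labelled for."""
    for c in classifications:
        if c.label not in LABELS:
            raise AssertionError(f"{c.gene_id}: unknown label {c.label!r}")
        if c.label == "conserved_mini_driver" and not c.omega_pass < 1:
            raise AssertionError(
                f"{c.gene_id}: conserved mini-driver with omega_pass >= 1"
            )


def write_results(
    classifications: list[GeneClassification],
    out_dir,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write deterministic gene-sorted result tables and a run manifest.

    Emits all_genes.tsv, drivers.tsv, mini_drivers.tsv,
    conserved_mini_drivers.tsv (the driver table excludes
    dubious-filtered genes) and manifest.txt (flat key=value lines).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = classifications_frame(classifications)
    paths = {}

    def emit(name: str, sub: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        sub.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path

    emit("all_genes", df)
    emit("drivers", df[(df["label"] == "driver") & ~df["dubious_filtered"]])
    emit(
        "mini_drivers",
        df[df["label"].isin(["mini_driver", "conserved_mini_driver"])],
    )
    emit("conserved_mini_drivers", df[df["label"] == "conserved_mini_driver"])

    manifest = dict(manifest or {})
    manifest.setdefault("n_genes", len(df))
    manifest.setdefault("python", sys.version.split()[0])
    lines = [f"{k}={manifest[k]}" for k in sorted(manifest)]
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    paths["manifest"] = out_dir / "manifest.txt"
    return paths
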