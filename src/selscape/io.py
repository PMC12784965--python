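"""Ingestion of MAF-style mutation tables and CDS FASTA.

Reads the MC3-dialect MAF columns by default, selects one coding
transcript per gene, re-annotates each mutation against the CDS
(consequence from the genetic code, trinucleotide context class), and
applies the cohort-level hypermutator filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetics import BASE_INDEX, CONSEQUENCE_NAMES, STOP_CODONS, consequence
from .spectrum import collapse_context

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A required input column or option could not be resolved."""


class InputError(ValueError):
    """An input file was unusable."""


class RefMismatchError(ValueError):
    """MAF reference allele disagrees with the CDS sequence."""


#: default MC3 MAF column names
MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "transcript": "Transcript_ID",
    "variant_class": "Variant_Classification",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "position": "CDS_position",
}

_REQUIRED = ("sample", "gene", "variant_class", "ref", "alt", "position")

#: MAF Variant_Classification -> consequence string
VARIANT_CLASS_MAP = {
    "Silent": "synonymous",
    "Missense_Mutation": "missense",
}

_HGVSC_RE = re.compile(r"^c\.(\d+)[ACGT]>[ACGT]$")

RECORD_COLUMNS = [
    "sample_id",
    "gene_id",
    "transcript_id",
    "cds_position",
    "codon_index",
    "ref_base",
    "alt_base",
    "consequence",
    "context_class",
]


@dataclass(frozen=True)
class SomaticMutationRecord:
    """One annotated coding somatic mutation."""

    sample_id: str
    gene_id: str
    transcript_id: str
    cds_position: int  # 1-based within the CDS
    codon_index: int  # 1-based
    ref_base: str
    alt_base: str
    consequence: str  # synonymous | missense | other
    context_class: str | None = None


@dataclass
class CodingTranscript:
    """A gene's selected CDS (terminal stop excluded from site accounting)."""

    gene_id: str
    transcript_id: str
    cds_sequence: str
    n_codons: int = field(init=False)

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} "
                "not divisible by 3"
            )
        n = len(self.cds_sequence) // 3
        if self.cds_sequence[-3:] in STOP_CODONS:
            n -= 1
        self.n_codons = n


@dataclass
class CohortDataset:
    """Annotated mutation records plus per-sample bookkeeping."""

    records: pd.DataFrame  # columns RECORD_COLUMNS
    samples: pd.DataFrame  # sample_id, cancer_type, n_mutations
    excluded_samples: pd.DataFrame  # sample_id, cancer_type, n_mutations, reason


def _parse_position(value) -> int | None:
    """Parse a CDS position given as int, '123', '123/1182' or 'c.123A>G'."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (int, np.integer)):
        return int(value)
    text = str(value).strip()
    if not text or text in (".", "-", "nan"):
        return None
    if text.isdigit():
        return int(text)
    if "/" in text:
        head = text.split("/", 1)[0]
        if head.isdigit():
            return int(head)
    m = _HGVSC_RE.match(text)
    if m:
        return int(m.group(1))
    return None


def read_maf(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a MAF-style TSV into a normalised raw-mutation table.

    Returns a DataFrame with columns sample_id, gene_id, transcript_id,
    variant_class, consequence (mapped from the classification string),
    ref_base, alt_base, cds_position (nullable Int64).  Rows with an
    unmappable classification are retained with consequence "other".
    """
    columns = dict(MAF_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for key in _REQUIRED:
        name = columns[key]
        if name not in df.columns:
            if key == "position" and "HGVSc" in df.columns:
                continue  # fall back to HGVSc below
            raise ConfigurationError(
                f"required MAF column {name!r} (role: {key}) not found"
            )
    out = pd.DataFrame(
        {
            "sample_id": df[columns["sample"]],
            "gene_id": df[columns["gene"]],
            "transcript_id": df[columns["transcript"]]
            if columns["transcript"] in df.columns
            else pd.Series([""] * len(df), dtype=str),
            "variant_class": df[columns["variant_class"]],
            "ref_base": df[columns["ref"]].str.upper(),
            "alt_base": df[columns["alt"]].str.upper(),
        }
    )
    pos_col = columns["position"] if columns["position"] in df.columns else "HGVSc"
    out["cds_position"] = (
        df[pos_col].map(_parse_position).astype("Int64")
        if len(df)
        else pd.Series([], dtype="Int64")
    )
    out["consequence"] = out["variant_class"].map(VARIANT_CLASS_MAP).fillna("other")
    return out


def read_cds_fasta(path, transcript_table: dict | None = None) -> dict:
    """Read CDS FASTA, keeping exactly one transcript per gene.

    Headers must carry gene and transcript identifiers: either
    ``>transcript_id gene:gene_id`` (Ensembl-like) or
    ``>gene_id|transcript_id``.  When ``transcript_table`` (gene_id ->
    transcript_id) names a transcript it wins; otherwise the longest CDS
    is kept (ties broken by lexicographically smallest transcript_id).
    Records whose length is not divisible by 3 are skipped with a warning.

    Returns {gene_id: CodingTranscript}.
    """
    candidates: dict[str, list[CodingTranscript]] = {}
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        gene_id, transcript_id = _parse_fasta_header(rec.id, rec.description)
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            logger.warning(
                "skipping %s (%s): CDS length %d not divisible by 3",
                transcript_id,
                gene_id,
                len(seq),
            )
            continue
        if any(b not in BASE_INDEX for b in seq):
            logger.warning(
                "skipping %s (%s): non-ACGT bases in CDS", transcript_id, gene_id
            )
            continue
        candidates.setdefault(gene_id, []).append(
            CodingTranscript(gene_id, transcript_id, seq)
        )
    if n_parsed == 0:
        raise InputError(f"no parseable FASTA record in {path}")

    selected: dict[str, CodingTranscript] = {}
    for gene_id, txs in candidates.items():
        wanted = (transcript_table or {}).get(gene_id)
        chosen = None
        if wanted is not None:
            chosen = next((t for t in txs if t.transcript_id == wanted), None)
            if chosen is None:
                logger.warning(
                    "gene %s: requested transcript %s not in FASTA; "
                    "falling back to longest CDS",
                    gene_id,
                    wanted,
                )
        if chosen is None:
            chosen = min(txs, key=lambda t: (-len(t.cds_sequence), t.transcript_id))
        selected[gene_id] = chosen
    return selected


def _parse_fasta_header(rec_id: str, description: str) -> tuple[str, str]:
    if "|" in rec_id:
        gene_id, transcript_id = rec_id.split("|", 1)
        return gene_id, transcript_id
    m = re.search(r"gene[:=](\S+)", description)
    if m:
        return m.group(1), rec_id
    # last resort: the record id doubles as the gene id
    return rec_id, rec_id


def annotate_mutation(
    transcript: CodingTranscript,
    cds_position: int,
    ref: str,
    alt: str,
    sample_id: str = "",
    flank5: str | None = None,
    flank3: str | None = None,
) -> SomaticMutationRecord:
    """Annotate one substitution against the transcript CDS.

    Consequence is recomputed from the genetic code (stop-gain/-loss map
    to "other").  The context class uses the CDS itself for interior
    positions and the supplied flanks at CDS edges; it is None when a
    flank is unavailable.  Raises ``RefMismatchError`` when the MAF
    reference allele disagrees with the CDS and ``ValueError`` when the
    position is outside the coding range.
    """
    cds = transcript.cds_sequence
    n_coding = 3 * transcript.n_codons
    if not 1 <= cds_position <= n_coding:
        raise ValueError(
            f"{transcript.gene_id}: CDS position {cds_position} outside 1..{n_coding}"
        )
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    p = cds_position - 1
    if cds[p] != ref:
        raise RefMismatchError(
            f"{transcript.gene_id}:{cds_position} MAF ref {ref} != CDS {cds[p]}"
        )
    codon_i = p // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    cons = consequence(codon, p % 3, alt)

    left = cds[p - 1] if p >= 1 else flank5
    right = cds[p + 1] if p + 1 < len(cds) else flank3
    context = (
        collapse_context(left, ref, alt, right)
        if (left is not None and right is not None)
        else None
    )
    return SomaticMutationRecord(
        sample_id=sample_id,
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        cds_position=cds_position,
        codon_index=codon_i + 1,
        ref_base=ref,
        alt_base=alt,
        consequence=CONSEQUENCE_NAMES[cons],
        context_class=context,
    )


def annotate_cohort(
    raw: pd.DataFrame,
    transcripts: dict,
    cancer_types: pd.DataFrame | None = None,
) -> CohortDataset:
    """Annotate raw MAF rows against the selected transcripts.

    Rows whose gene lacks a transcript or whose CDS position is missing
    are dropped from the record table (they still count toward per-sample
    mutation totals).  Reference-mismatch rows are dropped with a logged
    count.
    """
    rows = []
    n_mismatch = n_skipped = 0
    for tup in raw.itertuples(index=False):
        tx = transcripts.get(tup.gene_id)
        pos = tup.cds_position
        if tx is None or pd.isna(pos):
            n_skipped += 1
            continue
        if (
            not isinstance(tup.ref_base, str)
            or not isinstance(tup.alt_base, str)
            or len(tup.ref_base) != 1
            or len(tup.alt_base) != 1
            or tup.ref_base not in BASE_INDEX
            or tup.alt_base not in BASE_INDEX
        ):
            n_skipped += 1  # indels / non-SNV rows
            continue
        try:
            rec = annotate_mutation(
                tx, int(pos), tup.ref_base, tup.alt_base, sample_id=tup.sample_id
            )
        except RefMismatchError:
            n_mismatch += 1
            continue
        except ValueError:
            n_skipped += 1
            continue
        rows.append(rec)
    if n_mismatch:
        logger.warning("dropped %d mutations with MAF/CDS reference mismatch", n_mismatch)
    if n_skipped:
        logger.info("skipped %d rows without usable CDS annotation", n_skipped)

    records = records_to_frame(rows)
    counts = raw.groupby("sample_id").size() if len(raw) else pd.Series(dtype=int)
    samples = pd.DataFrame(
        {"sample_id": counts.index, "n_mutations": counts.to_numpy()}
    )
    if cancer_types is not None:
        samples = samples.merge(cancer_types, on="sample_id", how="left")
    if "cancer_type" not in samples.columns:
        samples["cancer_type"] = pd.NA
    excluded = samples.iloc[0:0].copy()
    excluded["reason"] = pd.Series(dtype=str)
    return CohortDataset(records=records, samples=samples, excluded_samples=excluded)


def filter_hypermutators(cohort: CohortDataset) -> CohortDataset:
    """Exclude hypermutator samples via the per-cancer-type Tukey fence.

    Within each cancer type, a sample is excluded iff its total mutation
    count exceeds Q3 + 1.5*IQR of the stratum AND exceeds 1000; both
    conditions are required.  Strata with fewer than 4 samples use the
    whole-cohort fence.  Samples without a cancer type form their own
    stratum.  Idempotent: re-filtering removes nothing further.
    """
    samples = cohort.samples.copy()
    if len(samples) == 0:
        return cohort
    counts = samples["n_mutations"].to_numpy(dtype=float)
    q3_all, q1_all = np.percentile(counts, [75, 25])
    fence_all = q3_all + 1.5 * (q3_all - q1_all)

    fences = np.empty(len(samples))
    strata = samples["cancer_type"].fillna("__untyped__")
    for stratum, idx in samples.groupby(strata).groups.items():
        sub = samples.loc[idx, "n_mutations"].to_numpy(dtype=float)
        if len(sub) < 4:
            logger.info(
                "stratum %s has %d samples; using whole-cohort fence", stratum, len(sub)
            )
            fences[samples.index.get_indexer(idx)] = fence_all
        else:
            q3, q1 = np.percentile(sub, [75, 25])
            fences[samples.index.get_indexer(idx)] = q3 + 1.5 * (q3 - q1)

    hyper = (samples["n_mutations"].to_numpy() > fences) & (
        samples["n_mutations"].to_numpy() > 1000
    )
    newly_excluded = samples.loc[hyper].copy()
    newly_excluded["reason"] = "hypermutator"
    kept = samples.loc[~hyper]
    records = cohort.records[
        cohort.records["sample_id"].isin(set(kept["sample_id"]))
    ].reset_index(drop=True)
    excluded = pd.concat(
        [cohort.excluded_samples, newly_excluded], ignore_index=True
    )
    return CohortDataset(records=records, samples=kept.reset_index(drop=True),
                         excluded_samples=excluded)


def records_to_frame(records: list[SomaticMutationRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (
                r.sample_id,
                r.gene_id,
                r.transcript_id,
                r.cds_position,
                r.codon_index,
                r.ref_base,
                r.alt_base,
                r.consequence,
                r.context_class,
            )
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    df["cds_position"] = df["cds_position"].astype("int64" if len(df) else "int64")
    df["codon_index"] = df["codon_index"].astype("int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[SomaticMutationRecord]:
    return [
        SomaticMutationRecord(
            sample_id=row.sample_id,
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            cds_position=int(row.cds_position),
            codon_index=int(row.codon_index),
            ref_base=row.ref_base,
            alt_base=row.alt_base,
            consequence=row.consequence,
            context_class=None if pd.isna(row.context_class) else row.context_class,
        )
        for row in df.itertuples(index=False)
    ]


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=RECORD_COLUMNS)


def read_records_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in RECORD_COLUMNS if c not in ("cds_position", "codon_index")},
    )
    df["cds_position"] = df["cds_position"].astype("int64")
    df["codon_index"] = df["codon_index"].astype("int64")
    return df[RECORD_COLUMNS]
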