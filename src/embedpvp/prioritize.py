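"""Variant prioritization pipeline.

Given a patient's candidate variants (VCF + Annovar-style annotation table),
a phenotype profile, and any trained embedding channel, the pipeline

1. filters to rare variants (max population MAF strictly below the threshold,
   default 1%; missing MAF counts as rare),
2. assigns each variant to its containing gene(s) — or the nearest gene(s)
   when intergenic, with ties going to all tied genes,
3. computes MS, the maximum gene–patient phenotype similarity over the
   assigned genes under the chosen embedding channel,
4. computes GP, the pathogenicity score (CADD, PHRED-like) min–max normalized
   within the patient's candidate set so it is commensurate with MS,
5. combines them as S = w*MS + (1-w)*GP (default w = 0.5), and
6. emits the deterministically ranked variant list (descending S, ties broken
   by descending GP then by genomic coordinate).

Coordinates: VCF positions are 1-based inclusive; gene intervals are 0-based
half-open.  The conversion happens in :func:`assign_genes` only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REGION_TYPES = ("exonic", "intronic", "intergenic", "other")
MAF_SOURCES = ("maf_1kg", "maf_exac", "maf_gnomad")

ANNOTATION_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "genes", "region_type",
    "maf_1kg", "maf_exac", "maf_gnomad", "cadd",
]


@dataclass
class Variant:
    """One candidate variant joined to its annotations.

    ``maf_by_source`` maps population database name to allele frequency in
    [0, 1]; ``cadd`` is the raw PHRED-like deleteriousness score (None when
    the annotation is missing).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    region_type: str = "other"
    genes: list[str] = field(default_factory=list)
    maf_by_source: dict[str, float] = field(default_factory=dict)
    cadd: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("POS is 1-based and must be >= 1")
        for source, value in self.maf_by_source.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"MAF {source}={value} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class RankedVariant:
    variant: Variant
    MS: float
    GP: float
    S: float
    rank: int
    flags: list[str] = field(default_factory=list)


class GeneModel:
    """Gene intervals per chromosome; [start, end) 0-based half-open."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if missing := required - set(table.columns):
            raise ValueError(f"gene model missing columns {sorted(missing)}")
        if (table["start"] >= table["end"]).any():
            raise ValueError("gene intervals require start < end")
        self.table = table.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, sub in table.groupby("chrom", sort=True):
            tree = IntervalTree()
            for row in sub.itertuples(index=False):
                tree.addi(int(row.start), int(row.end), row.gene_id)
            self._trees[str(chrom)] = tree
            self._by_chrom[str(chrom)] = sub.reset_index(drop=True)

    def interval(self, gene_id: str) -> tuple[str, int, int]:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModel":
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str},
        )
        return cls(bed[["gene_id", "chrom", "start", "end", "strand"]])


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    keys = table[["chrom", "pos", "ref", "alt"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (chrom, pos, ref, alt) annotation keys")
    return table


def _variant_from_row(chrom: str, pos: int, ref: str, alt: str, row) -> Variant:
    if row is None:
        return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
    mafs = {}
    for source in MAF_SOURCES:
        value = row[source]
        if pd.notna(value):
            mafs[source] = float(value)
    genes = []
    if pd.notna(row["genes"]) and str(row["genes"]):
        genes = str(row["genes"]).split(",")
    cadd = float(row["cadd"]) if pd.notna(row["cadd"]) else None
    region = str(row["region_type"]) if pd.notna(row["region_type"]) else "other"
    return Variant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, region_type=region,
        genes=genes, maf_by_source=mafs, cadd=cadd,
    )


def read_patient_vcf(vcf_path: str | Path, annotation_path: str | Path) -> list[Variant]:
    """One Variant per VCF record/ALT allele, left-joined to its annotation row.

    Multi-allelic records are decomposed into per-ALT variants.  Records with
    no matching annotation row become unannotated variants with a warning.
    """
    from cyvcf2 import VCF

    table = read_annotation_table(annotation_path)
    lookup = {
        key: table.iloc[i]
        for i, key in enumerate(
            zip(table["chrom"].astype(str), table["pos"].astype(int),
                table["ref"].astype(str), table["alt"].astype(str))
        )
    }
    variants: list[Variant] = []
    unmatched = 0
    for record in VCF(str(vcf_path)):
        for alt in record.ALT:
            key = (str(record.CHROM), int(record.POS), str(record.REF), str(alt))
            row = lookup.get(key)
            if row is None:
                unmatched += 1
            variants.append(_variant_from_row(*key, row))
    if unmatched:
        warnings.warn(f"{unmatched} VCF records had no annotation row")
    return variants


def variants_from_table(table: pd.DataFrame) -> list[Variant]:
    """Build Variant objects straight from an annotation-style DataFrame."""
    return [
        _variant_from_row(str(row["chrom"]), int(row["pos"]), str(row["ref"]),
                          str(row["alt"]), row)
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def filter_rare(variants: Sequence[Variant], threshold: float = 0.01) -> list[Variant]:
    """Keep variants whose maximum MAF over sources is strictly below the
    threshold; a variant with no MAF annotation counts as rare."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("MAF threshold must be in (0, 1]")
    kept = []
    for v in variants:
        max_maf = max(v.maf_by_source.values(), default=0.0)
        if max_maf < threshold:
            kept.append(v)
    return kept


def assign_genes(variant: Variant, gene_model: GeneModel) -> list[str]:
    """Containing gene(s) of the variant, or the nearest gene(s) on the same
    chromosome (all genes at the minimal distance) when outside every
    interval.  VCF 1-based POS is converted to a 0-based coordinate here."""
    pos0 = variant.pos - 1
    tree = gene_model._trees.get(variant.chrom)
    if tree is None:
        warnings.warn(f"chromosome {variant.chrom!r} absent from the gene model")
        return []
    hits = sorted(iv.data for iv in tree[pos0])
    if hits:
        return hits
    sub = gene_model._by_chrom[variant.chrom]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    dist = np.maximum(starts - pos0, pos0 - (ends - 1))
    best = dist.min()
    return sorted(sub.loc[dist == best, "gene_id"])


def compute_MS(
    variant: Variant,
    patient_id: str,
    scorer: Callable[[str, str], float | None],
) -> tuple[float, bool]:
    """Maximum gene–patient similarity over the variant's assigned genes.

    Genes the channel cannot score are skipped; if every gene is unscorable
    (or none is assigned) MS is 0 and the flag is set.
    """
    scores = []
    for gene in variant.genes:
        s = scorer(gene, patient_id)
        if s is not None:
            scores.append(float(s))
    if not scores:
        return 0.0, True
    return max(scores), False


def normalize_GP(variants: Sequence[Variant], mode: str = "minmax") -> np.ndarray:
    """Normalized pathogenicity per variant.

    ``minmax``: min–max over the candidate set's raw CADD values (all-equal
    values map to 0.5).  ``phred``: raw/100 clipped to [0, 1].  A missing CADD
    maps to 0 in either mode.
    """
    raw = np.array(
        [v.cadd if v.cadd is not None else np.nan for v in variants], dtype=float
    )
    gp = np.zeros(len(raw))
    have = ~np.isnan(raw)
    if not have.any():
        return gp
    if mode == "phred":
        gp[have] = np.clip(raw[have] / 100.0, 0.0, 1.0)
        return gp
    if mode != "minmax":
        raise ValueError(f"unknown GP normalization {mode!r}")
    lo, hi = raw[have].min(), raw[have].max()
    gp[have] = 0.5 if hi == lo else (raw[have] - lo) / (hi - lo)
    return gp


def combine(MS: float, GP: float, w: float = 0.5) -> float:
    """Weighted average S = w*MS + (1-w)*GP."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    return w * MS + (1.0 - w) * GP


def rank_variants(
    scored: Sequence[tuple[Variant, float, float, float, list[str]]]
) -> list[RankedVariant]:
    """Deterministic ranking: descending S, then descending GP, then
    (chrom, pos, ref, alt) lexicographic."""
    order = sorted(
        scored, key=lambda item: (-item[3], -item[2], item[0].key)
    )
    return [
        RankedVariant(variant=v, MS=ms, GP=gp, S=s, rank=i + 1, flags=flags)
        for i, (v, ms, gp, s, flags) in enumerate(order)
    ]


def rank_patient(
    variants: Sequence[Variant],
    patient_id: str,
    scorer: Callable[[str, str], float | None],
    gene_model: GeneModel | None = None,
    w: float = 0.5,
    maf_threshold: float = 0.01,
    gp_mode: str = "minmax",
) -> list[RankedVariant]:
    """Full pipeline: MAF filter, gene assignment, MS/GP/S, ranking."""
    candidates = filter_rare(variants, maf_threshold)
    if gene_model is not None:
        for v in candidates:
            v.genes = assign_genes(v, gene_model)
    gp = normalize_GP(candidates, mode=gp_mode)
    scored = []
    for v, gp_v in zip(candidates, gp):
        ms, unscorable = compute_MS(v, patient_id, scorer)
        flags = []
        if unscorable:
            flags.append("no_scorable_gene")
        if v.cadd is None:
            flags.append("missing_cadd")
        scored.append((v, ms, float(gp_v), combine(ms, float(gp_v), w), flags))
    return rank_variants(scored)


def write_ranking(ranked: Sequence[RankedVariant], path: str | Path) -> None:
    """Output TSV: rank chrom pos ref alt genes MS GP S flags (6-decimal)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tchrom\tpos\tref\talt\tgenes\tMS\tGP\tS\tflags\n")
        for rv in ranked:
            v = rv.variant
            fh.write(
                f"{rv.rank}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{','.join(v.genes)}\t{rv.MS:.6f}\t{rv.GP:.6f}\t{rv.S:.6f}\t"
                f"{';'.join(rv.flags)}\n"
            )
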