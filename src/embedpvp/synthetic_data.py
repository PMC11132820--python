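"""Synthetic knowledge base, background genome and patient cohort generators.

The generator emulates, at desk scale, every input the prioritizer consumes:

* a phenotype ontology shaped as a rooted DAG (tree plus occasional extra
  parents), emitted as NF1 subclass axioms;
* diseases with phenotype profiles and genes with annotation profiles; each
  disease's causative gene shares a configurable ``overlap`` fraction of the
  disease profile, part of which is generalized to parent classes so that
  subclass axioms carry signal (``parent_signal_fraction``);
* a background genome of rare variants (default 100 000; 90% intronic / 10%
  exonic, max MAF strictly below 1% in post-filter mode) placed consistently
  with an emitted gene model, with CADD drawn from a benign-low /
  pathogenic-high two-component mixture;
* synthetic patients: the background plus one spiked exonic causative variant
  inside the disease's gene (high-tail CADD), paired with the disease's
  phenotype profile under a configurable noise model (each noised term is
  replaced by a random class or generalized to a parent, equal probability).

Everything is deterministic under the config seed: regenerating a cohort
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge_base import (
    HAS_PHENOTYPE,
    Axiom,
    AnnotationSet,
    NF1,
    Ontology,
    write_axioms,
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SynthConfig:
    """Study-condition knobs for the synthetic cohort.

    ``overlap`` is the fraction of a disease's phenotype profile that its
    causative gene's annotations share (directly or via a parent class);
    ``noise`` the fraction of a patient's phenotype terms replaced or
    generalized; ``n_variants`` the background size (90% intronic by default,
    all rare in post-filter mode, ``prefilter=True`` draws unfiltered MAFs).
    """

    n_phenotypes: int = 150
    branching: int = 3
    extra_parent_prob: float = 0.10
    n_genes: int = 200
    n_diseases: int = 20
    phenotypes_per_disease: int = 8
    annotations_per_gene: int = 8
    overlap: float = 0.8
    parent_signal_fraction: float = 0.5
    noise: float = 0.1
    n_variants: int = 100_000
    intronic_fraction: float = 0.90
    maf_beta: tuple[float, float] = (0.5, 300.0)
    prefilter_maf_beta: tuple[float, float] = (0.3, 10.0)
    prefilter: bool = False
    benign_cadd: tuple[float, float] = (2.0, 2.5)  # gamma shape, scale
    pathogenic_cadd: tuple[float, float] = (24.0, 5.0)  # normal mean, sd
    pathogenic_fraction: float = 0.025
    spike_cadd: tuple[float, float] = (27.0, 2.0)
    gene_length: int = 3000
    exon_fraction: float = 0.3
    intergenic_gap: int = 2000
    n_patients: int | None = None  # default: one patient per disease
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap", "parent_signal_fraction", "noise",
                     "intronic_fraction", "exon_fraction", "pathogenic_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_phenotypes", "n_genes", "n_diseases", "n_variants",
                     "phenotypes_per_disease", "annotations_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class KBData:
    ontology: Ontology
    annotations: AnnotationSet  # associations = all planted pairs
    disease_profiles: dict[str, list[str]]
    causative_gene: dict[str, str]
    parents: dict[str, list[str]]


@dataclass
class Patient:
    patient_id: str
    disease_id: str
    variants: pd.DataFrame  # annotation-table layout, background + spike
    phenotypes: list[str]
    truth: dict


@dataclass
class Cohort:
    config: SynthConfig
    kb: KBData
    gene_model: pd.DataFrame
    background: pd.DataFrame
    patients: list[Patient] = field(default_factory=list)


def _phenotype_id(i: int) -> str:
    return f"PH:{i:04d}"


def make_kb(cfg: SynthConfig, rng: np.random.Generator | None = None) -> KBData:
    """Phenotype DAG + gene/disease annotation profiles + planted associations.

    The DAG is built breadth-first with ``branching`` children per node plus
    occasional extra parents; every parent link is one NF1 subclass axiom.
    The causative gene of disease ``i`` is gene ``i``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_overlap = round(cfg.overlap * cfg.phenotypes_per_disease)
    if n_overlap > cfg.annotations_per_gene:
        raise ValueError(
            "overlap * phenotypes_per_disease exceeds annotations_per_gene"
        )

    classes = [_phenotype_id(i) for i in range(cfg.n_phenotypes)]
    parents: dict[str, list[str]] = {classes[0]: []}
    depth = {classes[0]: 0}
    frontier = [classes[0]]
    next_child = 1
    while next_child < cfg.n_phenotypes:
        new_frontier = []
        for parent in frontier:
            for _ in range(cfg.branching):
                if next_child >= cfg.n_phenotypes:
                    break
                child = classes[next_child]
                next_child += 1
                parents[child] = [parent]
                depth[child] = depth[parent] + 1
                # occasional extra parent among earlier non-ancestor classes
                if rng.random() < cfg.extra_parent_prob and next_child > 2:
                    extra = classes[int(rng.integers(1, len(parents)))]
                    if extra != child and extra not in parents[child]:
                        parents[child].append(extra)
                new_frontier.append(child)
        frontier = new_frontier or [classes[0]]

    ontology = Ontology()
    for child, plist in parents.items():
        for parent in plist:
            ontology.register_axiom(Axiom(NF1, (child, parent)))

    deep = [c for c in classes if depth[c] >= 2] or classes[1:]
    genes = [f"GENE:{i:04d}" for i in range(cfg.n_genes)]
    diseases = [f"DIS:{i:04d}" for i in range(cfg.n_diseases)]

    disease_profiles: dict[str, list[str]] = {}
    gene_rows: list[tuple[str, str, str]] = []
    causative: dict[str, str] = {}
    for i, disease in enumerate(diseases):
        profile = sorted(
            rng.choice(deep, size=min(cfg.phenotypes_per_disease, len(deep)),
                       replace=False)
        )
        disease_profiles[disease] = profile
        causative[disease] = genes[i]
        shared = list(rng.choice(profile, size=min(n_overlap, len(profile)),
                                 replace=False))
        n_parent = round(cfg.parent_signal_fraction * len(shared))
        annot = []
        for j, cls in enumerate(shared):
            if j < n_parent and parents[cls]:
                annot.append(parents[cls][0])  # signal flows via the parent
            else:
                annot.append(cls)
        while len(annot) < cfg.annotations_per_gene:
            annot.append(str(rng.choice(deep)))
        gene_rows.extend((genes[i], HAS_PHENOTYPE, cls) for cls in annot)
    for gene in genes[cfg.n_diseases :]:
        picks = rng.choice(deep, size=min(cfg.annotations_per_gene, len(deep)),
                           replace=False)
        gene_rows.extend((gene, HAS_PHENOTYPE, cls) for cls in picks)

    disease_rows = [
        (d, HAS_PHENOTYPE, cls) for d in diseases for cls in disease_profiles[d]
    ]
    annotations = AnnotationSet(
        gene_annotations=pd.DataFrame(
            gene_rows, columns=["entity_id", "relation", "class_id"]
        ).drop_duplicates(ignore_index=True),
        disease_phenotypes=pd.DataFrame(
            disease_rows, columns=["entity_id", "relation", "class_id"]
        ),
        associations=pd.DataFrame(
            [(causative[d], d) for d in diseases],
            columns=["gene_id", "disease_id"],
        ),
    )
    ontology.individuals.update(genes)
    ontology.individuals.update(diseases)
    return KBData(ontology, annotations, disease_profiles, causative, parents)


# ---------------------------------------------------------------------------
# Background genome
# ---------------------------------------------------------------------------


def _make_gene_model(cfg: SynthConfig) -> pd.DataFrame:
    starts = 1000 + np.arange(cfg.n_genes) * (cfg.gene_length + cfg.intergenic_gap)
    exon_len = int(round(cfg.exon_fraction * cfg.gene_length))
    return pd.DataFrame(
        {
            "gene_id": [f"GENE:{i:04d}" for i in range(cfg.n_genes)],
            "chrom": "1",
            "start": starts,
            "end": starts + cfg.gene_length,
            "exon_end": starts + exon_len,  # [start, exon_end) is exonic
            "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-"),
        }
    )


def _draw_maf(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b = cfg.prefilter_maf_beta if cfg.prefilter else cfg.maf_beta
    maf = rng.beta(a, b, size=(n, 3))
    if not cfg.prefilter:
        # post-filter background: resample until every MAF is strictly rare
        for _ in range(1000):
            bad = maf >= 0.01
            if not bad.any():
                break
            maf[bad] = rng.beta(a, b, size=int(bad.sum()))
        else:
            raise RuntimeError("MAF truncation did not converge")
    return maf


def _draw_cadd(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    shape, scale = cfg.benign_cadd
    cadd = rng.gamma(shape, scale, size=n)
    hot = rng.random(n) < cfg.pathogenic_fraction
    mean, sd = cfg.pathogenic_cadd
    cadd[hot] = np.maximum(rng.normal(mean, sd, size=int(hot.sum())), 0.0)
    return np.round(cadd, 3)


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref], _BASES[alt]


def make_background_genome(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background variant table + gene model.

    Exactly ``round(intronic_fraction * n_variants)`` variants fall in intron
    regions and the remainder in exon regions of the emitted gene model; in
    post-filter mode every MAF is strictly below 1% (the background mimics a
    cohort already reduced to its rare variants), ``prefilter=True`` leaves
    common variants in for exercising the MAF filter.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    genes = _make_gene_model(cfg)
    n_intronic = round(cfg.intronic_fraction * cfg.n_variants)
    n_exonic = cfg.n_variants - n_intronic
    exon_pos = np.concatenate(
        [np.arange(s, e) for s, e in zip(genes["start"], genes["exon_end"])]
    )
    intron_pos = np.concatenate(
        [np.arange(s, e) for s, e in zip(genes["exon_end"], genes["end"])]
    )
    if n_exonic > len(exon_pos) or n_intronic > len(intron_pos):
        raise ValueError("n_variants too large for the synthetic gene model")
    pos0 = np.concatenate(
        [
            rng.choice(intron_pos, size=n_intronic, replace=False),
            rng.choice(exon_pos, size=n_exonic, replace=False),
        ]
    )
    region = np.array(["intronic"] * n_intronic + ["exonic"] * n_exonic)
    gene_idx = (pos0 - 1000) // (cfg.gene_length + cfg.intergenic_gap)
    gene_ids = genes["gene_id"].to_numpy()[gene_idx]
    ref, alt = _alleles(rng, cfg.n_variants)
    maf = _draw_maf(cfg, rng, cfg.n_variants)
    table = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos0 + 1,  # 1-based
            "ref": ref,
            "alt": alt,
            "genes": gene_ids,
            "region_type": region,
            "maf_1kg": np.round(maf[:, 0], 6),
            "maf_exac": np.round(maf[:, 1], 6),
            "maf_gnomad": np.round(maf[:, 2], 6),
            "cadd": _draw_cadd(cfg, rng, cfg.n_variants),
        }
    )
    table = table.sort_values("pos", kind="mergesort", ignore_index=True)
    return table, genes


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------


def _noisy_profile(
    profile: list[str],
    parents: dict[str, list[str]],
    classes: list[str],
    noise: float,
    rng: np.random.Generator,
) -> list[str]:
    """Replace exactly round(noise * |profile|) terms: each replaced term
    becomes a uniformly random class or its parent class (equal probability)."""
    out = list(profile)
    n_noise = round(noise * len(out))
    if n_noise == 0:
        return out
    idx = rng.choice(len(out), size=n_noise, replace=False)
    for i in idx:
        term = out[i]
        if rng.random() < 0.5 and parents.get(term):
            out[i] = parents[term][0]
        else:
            candidates = [c for c in classes if c != term]
            out[i] = str(candidates[int(rng.integers(len(candidates)))])
    return out


def make_patient(
    patient_id: str,
    disease_id: str,
    background: pd.DataFrame,
    gene_model: pd.DataFrame,
    kb: KBData,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> Patient:
    """Spike one exonic causative variant into a copy of the background and
    pair it with the disease's (noised) phenotype profile."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    gene = kb.causative_gene[disease_id]
    row = gene_model.loc[gene_model["gene_id"] == gene]
    if row.empty:
        raise ValueError(f"causative gene {gene!r} has no interval")
    start, exon_end = int(row.iloc[0]["start"]), int(row.iloc[0]["exon_end"])
    taken = set(background["pos"].tolist())
    for _ in range(10_000):
        pos = int(rng.integers(start, exon_end)) + 1
        if pos not in taken:
            break
    else:
        raise RuntimeError("no free exonic position for the causative spike")
    ref, alt = _alleles(rng, 1)
    mean, sd = cfg.spike_cadd
    cadd = round(max(float(rng.normal(mean, sd)), 0.0), 3)
    spike = pd.DataFrame(
        {
            "chrom": ["1"], "pos": [pos], "ref": [ref[0]], "alt": [alt[0]],
            "genes": [gene], "region_type": ["exonic"],
            "maf_1kg": [0.0], "maf_exac": [0.0], "maf_gnomad": [0.0],
            "cadd": [cadd],
        }
    )
    variants = (
        pd.concat([background, spike], ignore_index=True)
        .sort_values("pos", kind="mergesort", ignore_index=True)
    )
    classes = sorted(kb.parents)
    phenotypes = _noisy_profile(
        kb.disease_profiles[disease_id], kb.parents, classes, cfg.noise, rng
    )
    truth = {
        "patient_id": patient_id, "chrom": "1", "pos": pos,
        "ref": str(ref[0]), "alt": str(alt[0]), "gene": gene,
        "disease": disease_id,
    }
    return Patient(patient_id, disease_id, variants, phenotypes, truth)


def simulate_cohort(cfg: SynthConfig) -> Cohort:
    """Full deterministic cohort: KB, background, one patient per disease
    (cycled when ``n_patients`` exceeds the disease count)."""
    rng = np.random.default_rng(cfg.seed)
    kb = make_kb(cfg, np.random.default_rng(rng.integers(2**31)))
    background, gene_model = make_background_genome(
        cfg, np.random.default_rng(rng.integers(2**31))
    )
    n_patients = cfg.n_patients if cfg.n_patients is not None else cfg.n_diseases
    diseases = sorted(kb.disease_profiles)
    patients = [
        make_patient(
            f"PATIENT:{i:03d}",
            diseases[i % len(diseases)],
            background,
            gene_model,
            kb,
            cfg,
            np.random.default_rng(rng.integers(2**31)),
        )
        for i in range(n_patients)
    ]
    return Cohort(cfg, kb, gene_model, background, patients)


# ---------------------------------------------------------------------------
# File emission / loading
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=1>\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\n")


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit the cohort in the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_axioms(cohort.kb.ontology, outdir / "kb_axioms.tsv")
    ann = cohort.kb.annotations
    pd.concat([ann.gene_annotations, ann.disease_phenotypes]).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False
    )
    ann.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    bed = cohort.gene_model.copy()
    bed["score"] = 0
    bed[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        outdir / "genes.bed", sep="\t", index=False, header=False
    )
    write_vcf(cohort.background, outdir / "background.vcf")
    cohort.background.to_csv(outdir / "background.annot.tsv", sep="\t", index=False)
    patient_dir = outdir / "patients"
    patient_dir.mkdir(exist_ok=True)
    truths = []
    for patient in cohort.patients:
        stem = patient.patient_id.replace(":", "_")
        write_vcf(patient.variants, patient_dir / f"{stem}.vcf")
        patient.variants.to_csv(
            patient_dir / f"{stem}.annot.tsv", sep="\t", index=False
        )
        (patient_dir / f"{stem}.phenotypes.txt").write_text(
            ",".join(patient.phenotypes) + "\n"
        )
        truths.append(patient.truth)
    pd.DataFrame(truths).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def load_cohort(indir: str | Path, cfg: SynthConfig | None = None) -> Cohort:
    """Load a cohort previously written with :func:`write_cohort`.

    Gene vs disease annotation rows are separated by membership in the
    association table's gene/disease columns.
    """
    from .knowledge_base import parse_axioms, read_annotations, read_associations

    indir = Path(indir)
    ontology = parse_axioms(indir / "kb_axioms.tsv")
    annotations = read_annotations(indir / "annotations.tsv")
    associations = read_associations(indir / "associations.tsv")
    diseases = set(associations["disease_id"])
    is_disease = annotations["entity_id"].isin(diseases)
    ann = AnnotationSet(
        gene_annotations=annotations[~is_disease].reset_index(drop=True),
        disease_phenotypes=annotations[is_disease].reset_index(drop=True),
        associations=associations,
    )
    bed = pd.read_csv(
        indir / "genes.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    gene_model = bed[["gene_id", "chrom", "start", "end", "strand"]].copy()
    background = pd.read_csv(indir / "background.annot.tsv", sep="\t",
                             dtype={"chrom": str})
    truth = pd.read_csv(indir / "truth.tsv", sep="\t", dtype={"chrom": str})
    profiles = {
        d: sorted(sub["class_id"])
        for d, sub in ann.disease_phenotypes.groupby("entity_id")
    }
    causative = dict(
        associations[["disease_id", "gene_id"]].itertuples(index=False)
    )
    kb = KBData(ontology, ann, profiles, causative, parents={})
    patients = []
    for row in truth.itertuples(index=False):
        stem = str(row.patient_id).replace(":", "_")
        variants = pd.read_csv(
            indir / "patients" / f"{stem}.annot.tsv", sep="\t", dtype={"chrom": str}
        )
        phenotypes = (
            (indir / "patients" / f"{stem}.phenotypes.txt")
            .read_text().strip().split(",")
        )
        patients.append(
            Patient(
                patient_id=str(row.patient_id),
                disease_id=str(row.disease),
                variants=variants,
                phenotypes=phenotypes,
                truth=row._asdict(),
            )
        )
    return Cohort(cfg or SynthConfig(), kb, gene_model, background, patients)
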