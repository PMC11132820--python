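"""Symbolic knowledge base: EL-normal-form axioms, annotations, and graph projection.

The knowledge base couples three ingredients:

* an ontology given by a signature ``(C, R, I)`` (concept, role and individual
  names) together with axioms in the four EL normal forms
  ``C ⊑ D``, ``C ⊓ D ⊑ E``, ``C ⊑ ∃R.D`` and ``∃R.C ⊑ D``;
* entity annotations linking genes and diseases to ontology classes
  (phenotypes, functions, anatomical sites of expression);
* gene–disease associations used as the supervised signal.

For the graph-based embedding channels the ontology is *projected* onto a
labeled directed multigraph ``G = (V, E, L)`` by a fixed rule set (the shared
structural core of the DL2Vec/OWL2Vec* projections); annotation rows and the
training-partition associations become labeled edges of the same graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: canonical edge / relation labels
SUBCLASSOF = "subclassof"
IS_ASSOCIATED_WITH = "is_associated_with"
HAS_PHENOTYPE = "has_phenotype"

NF1, NF2, NF3, NF4 = "nf1", "nf2", "nf3", "nf4"
_CONCEPT_ARITY = {NF1: 2, NF2: 3, NF3: 2, NF4: 2}


class AxiomParseError(ValueError):
    """Raised for a malformed axiom line; message names the line number."""


@dataclass(frozen=True)
class Axiom:
    """One axiom in EL normal form.

    ``concepts`` is the ordered tuple of concept names of the form
    (NF1: ``(C, D)`` for ``C ⊑ D``; NF2: ``(C, D, E)`` for ``C ⊓ D ⊑ E``;
    NF3: ``(C, D)`` for ``C ⊑ ∃R.D``; NF4: ``(C, D)`` for ``∃R.C ⊑ D``);
    ``role`` is the role name for NF3/NF4 and ``None`` otherwise.
    """

    form: str
    concepts: tuple[str, ...]
    role: str | None = None

    def __post_init__(self) -> None:
        if self.form not in _CONCEPT_ARITY:
            raise ValueError(f"unknown normal form {self.form!r}")
        if len(self.concepts) != _CONCEPT_ARITY[self.form]:
            raise ValueError(
                f"{self.form} expects {_CONCEPT_ARITY[self.form]} concepts, "
                f"got {len(self.concepts)}"
            )
        needs_role = self.form in (NF3, NF4)
        if needs_role and not self.role:
            raise ValueError(f"{self.form} requires a role")
        if not needs_role and self.role is not None:
            raise ValueError(f"{self.form} takes no role")


@dataclass
class Ontology:
    """Signature (concepts, roles, individuals) plus a duplicate-free axiom list."""

    concepts: set[str] = field(default_factory=set)
    roles: set[str] = field(default_factory=set)
    individuals: set[str] = field(default_factory=set)
    axioms: list[Axiom] = field(default_factory=list)

    def register_axiom(self, axiom: Axiom) -> bool:
        """Add ``axiom`` (and register its IDs); returns False for a duplicate."""
        if axiom in set(self.axioms):
            return False
        self.axioms.append(axiom)
        self.concepts.update(axiom.concepts)
        if axiom.role is not None:
            self.roles.add(axiom.role)
        return True

    def axiom_counts(self) -> dict[str, int]:
        counts = {NF1: 0, NF2: 0, NF3: 0, NF4: 0}
        for ax in self.axioms:
            counts[ax.form] += 1
        return counts


def _parse_axiom_fields(fields: Sequence[str], lineno: int) -> Axiom:
    n = len(fields)
    if n == 3 and fields[1] == SUBCLASSOF:
        return Axiom(NF1, (fields[0], fields[2]))
    if n == 5 and fields[1] == "and" and fields[3] == SUBCLASSOF:
        return Axiom(NF2, (fields[0], fields[2], fields[4]))
    if n == 5 and fields[1] == SUBCLASSOF and fields[2] == "some":
        return Axiom(NF3, (fields[0], fields[4]), role=fields[3])
    if n == 5 and fields[0] == "some" and fields[3] == SUBCLASSOF:
        return Axiom(NF4, (fields[2], fields[4]), role=fields[1])
    raise AxiomParseError(f"line {lineno}: unrecognized axiom dialect: {fields!r}")


def parse_axioms(path: str | Path) -> Ontology:
    """Parse an axiom TSV file (one normal-form axiom per line) into an Ontology.

    Duplicate lines are collapsed; blank lines and ``#`` comments are skipped.
    """
    ontology = Ontology()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            ontology.register_axiom(_parse_axiom_fields(line.split("\t"), lineno))
    return ontology


def axiom_to_line(axiom: Axiom) -> str:
    if axiom.form == NF1:
        c, d = axiom.concepts
        return f"{c}\t{SUBCLASSOF}\t{d}"
    if axiom.form == NF2:
        c, d, e = axiom.concepts
        return f"{c}\tand\t{d}\t{SUBCLASSOF}\t{e}"
    if axiom.form == NF3:
        c, d = axiom.concepts
        return f"{c}\t{SUBCLASSOF}\tsome\t{axiom.role}\t{d}"
    c, d = axiom.concepts
    return f"some\t{axiom.role}\t{c}\t{SUBCLASSOF}\t{d}"


def write_axioms(ontology: Ontology, path: str | Path) -> None:
    """Write axioms in canonical form: unique lines, lexicographically sorted."""
    lines = sorted({axiom_to_line(ax) for ax in ontology.axioms})
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Annotations and associations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["entity_id", "relation", "class_id"]
ASSOCIATION_COLUMNS = ["gene_id", "disease_id"]


@dataclass
class AnnotationSet:
    """Gene/disease ontology annotations plus gene–disease association pairs.

    ``associations`` holds the pairs intended for *training-graph* projection;
    validation/test partitions must be split off before constructing the graph
    so that held-out links never leak into the embedding substrate.
    """

    gene_annotations: pd.DataFrame
    disease_phenotypes: pd.DataFrame
    associations: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols in (
            (self.gene_annotations, ANNOTATION_COLUMNS),
            (self.disease_phenotypes, ANNOTATION_COLUMNS),
            (self.associations, ASSOCIATION_COLUMNS),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"missing columns {sorted(missing)}")
        if self.associations.duplicated(ASSOCIATION_COLUMNS).any():
            raise ValueError("association pairs must be unique")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)[ANNOTATION_COLUMNS]


def read_associations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)[ASSOCIATION_COLUMNS]


# ---------------------------------------------------------------------------
# Labeled graph and projection
# ---------------------------------------------------------------------------


class KnowledgeGraph:
    """Labeled directed multigraph ``G = (V, E, L)`` with ``E ⊆ V × L × V``."""

    def __init__(self) -> None:
        self.vertices: set[str] = set()
        self.labels: set[str] = set()
        self.edges: set[tuple[str, str, str]] = set()
        self.patient_profiles: dict[str, frozenset[str]] = {}
        self._adjacency: dict[str, list[tuple[str, str]]] | None = None

    def add_vertex(self, v: str) -> None:
        self.vertices.add(v)
        self._adjacency = None

    def add_edge(self, head: str, label: str, tail: str) -> None:
        self.vertices.add(head)
        self.vertices.add(tail)
        self.labels.add(label)
        self.edges.add((head, label, tail))
        self._adjacency = None

    def out_edges(self, v: str) -> list[tuple[str, str]]:
        """Outgoing ``(label, target)`` pairs of ``v`` in sorted (deterministic) order."""
        return self.adjacency().get(v, [])

    def adjacency(self) -> dict[str, list[tuple[str, str]]]:
        if self._adjacency is None:
            adj: dict[str, list[tuple[str, str]]] = {}
            for h, r, t in sorted(self.edges):
                adj.setdefault(h, []).append((r, t))
            self._adjacency = adj
        return self._adjacency

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        g.vertices = set(self.vertices)
        g.labels = set(self.labels)
        g.edges = set(self.edges)
        g.patient_profiles = dict(self.patient_profiles)
        return g

    def __len__(self) -> int:
        return len(self.edges)


def _axiom_edges(axiom: Axiom) -> list[tuple[str, str, str]]:
    """Projection rules for a single axiom.

    NF1 ``C ⊑ D``      -> (C, subclassof, D)
    NF2 ``C ⊓ D ⊑ E``  -> (C, subclassof, E), (D, subclassof, E)
    NF3 ``C ⊑ ∃R.D``   -> (C, R, D)
    NF4 ``∃R.C ⊑ D``   -> (C, R, D)
    """
    if axiom.form == NF1:
        c, d = axiom.concepts
        return [(c, SUBCLASSOF, d)]
    if axiom.form == NF2:
        c, d, e = axiom.concepts
        return [(c, SUBCLASSOF, e), (d, SUBCLASSOF, e)]
    c, d = axiom.concepts
    return [(c, axiom.role, d)]  # type: ignore[list-item]


def project_graph(
    ontology: Ontology,
    annotations: AnnotationSet | None = None,
    include_axioms: bool = True,
) -> KnowledgeGraph:
    """Project the knowledge base onto a labeled graph.

    With ``include_axioms=False`` every axiom-derived edge (including all
    subclass edges) is omitted and only annotation/association edges remain —
    the axiom-ablation configuration.  Annotation rows referencing classes
    absent from the ontology raise a warning but the edge is still created
    (merged annotation sources overlap imperfectly).
    """
    graph = KnowledgeGraph()
    for name in sorted(ontology.concepts | ontology.individuals):
        graph.add_vertex(name)
    if include_axioms:
        for axiom in ontology.axioms:
            for h, r, t in _axiom_edges(axiom):
                graph.add_edge(h, r, t)
    if annotations is not None:
        unknown: set[str] = set()
        for table in (annotations.gene_annotations, annotations.disease_phenotypes):
            for entity, relation, cls in table.itertuples(index=False):
                if cls not in ontology.concepts:
                    unknown.add(cls)
                graph.add_edge(entity, relation, cls)
        if unknown:
            warnings.warn(
                f"{len(unknown)} annotation class IDs missing from the ontology "
                "were registered as new vertices",
                stacklevel=2,
            )
        for gene, disease in annotations.associations[ASSOCIATION_COLUMNS].itertuples(
            index=False
        ):
            graph.add_edge(gene, IS_ASSOCIATED_WITH, disease)
    return graph


def attach_patients(
    graph: KnowledgeGraph,
    patients: Iterable[tuple[str, Iterable[str]]],
    relation: str = HAS_PHENOTYPE,
) -> KnowledgeGraph:
    """Add one vertex per patient plus a ``(patient, has_phenotype, class)`` edge
    per phenotype.  Idempotent per patient ID; re-attaching the same ID with a
    different phenotype set is an error.
    """
    for pid, phenotypes in patients:
        profile = frozenset(phenotypes)
        if pid in graph.patient_profiles:
            if graph.patient_profiles[pid] != profile:
                raise ValueError(
                    f"patient {pid!r} already attached with a different phenotype set"
                )
            continue
        graph.add_vertex(pid)
        if not profile:
            warnings.warn(f"patient {pid!r} has an empty phenotype set", stacklevel=2)
        for cls in sorted(profile):
            graph.add_edge(pid, relation, cls)
        graph.patient_profiles[pid] = profile
    return graph
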