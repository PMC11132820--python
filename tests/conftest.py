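"""Shared fixtures: tiny symbolic fixtures plus session-scoped trained models
on the default synthetic study conditions (200 genes, 20 diseases, overlap
0.8, noise 0.1, 2000-variant background)."""

import dataclasses

import pandas as pd
import pytest

from embedpvp.evaluate import (
    BenchmarkConfig,
    fit_channel,
    run_benchmark,
)
from embedpvp.knowledge_base import (
    AnnotationSet,
    KnowledgeGraph,
)
from embedpvp.model_core import split_associations
from embedpvp.synthetic_data import SynthConfig, simulate_cohort

SEED = 1

AXIOM_FIXTURE = """\
C\tsubclassof\tD
A\tand\tB\tsubclassof\tE
C\tsubclassof\tsome\tR\tD
some\tS\tA\tsubclassof\tB
"""


@pytest.fixture
def axiom_file(tmp_path):
    path = tmp_path / "axioms.tsv"
    path.write_text(AXIOM_FIXTURE)
    return path


@pytest.fixture
def toy_graph():
    g = KnowledgeGraph()
    g.add_edge("a", "r1", "b")
    g.add_edge("b", "r1", "c")
    g.add_edge("c", "r2", "a")
    g.add_edge("a", "r2", "c")
    g.add_vertex("island")
    return g


@pytest.fixture
def toy_annotations():
    return AnnotationSet(
        gene_annotations=pd.DataFrame(
            [("g1", "has_phenotype", "C"), ("g2", "has_phenotype", "D")],
            columns=["entity_id", "relation", "class_id"],
        ),
        disease_phenotypes=pd.DataFrame(
            [("d1", "has_phenotype", "C")],
            columns=["entity_id", "relation", "class_id"],
        ),
        associations=pd.DataFrame(
            [("g1", "d1")], columns=["gene_id", "disease_id"]
        ),
    )


# ---------------------------------------------------------------------------
# Session-scoped study-condition fixtures (shared by the acceptance tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_config():
    return SynthConfig(n_variants=2000)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return simulate_cohort(study_config)


@pytest.fixture(scope="session")
def bench_config():
    return BenchmarkConfig().seeded(SEED)


@pytest.fixture(scope="session")
def study_split(study_cohort, bench_config):
    train, val, test = split_associations(
        study_cohort.kb.annotations.associations, bench_config.split
    )
    heldout = pd.concat([val, test], ignore_index=True)
    return {"train": train, "val": val, "test": test, "heldout": heldout}


@pytest.fixture(scope="session")
def family_channels(study_cohort, study_split, bench_config):
    """One fitted channel per embedding family, trained on the KB without
    patients (the planted-recovery setting)."""
    return {
        method: fit_channel(
            method, study_cohort, study_split["train"], study_split["val"],
            bench_config,
        )
        for method in ("transe", "transd", "distmult", "dl2vec", "elem", "elbox")
    }


@pytest.fixture(scope="session")
def mode_results(study_cohort):
    """Transductive vs inductive end-to-end benchmark for TransE."""
    table = run_benchmark(
        study_cohort, methods=["transe"], modes=["transductive", "inductive"],
        seed=SEED,
    )
    return {row["mode"]: row for _, row in table.iterrows()}


@pytest.fixture(scope="session")
def ablation_results(study_cohort):
    """Transductive TransE with vs without ontology axiom edges."""
    out = {}
    for include in (True, False):
        cfg = dataclasses.replace(BenchmarkConfig(), include_axioms=include)
        table = run_benchmark(
            study_cohort, methods=["transe"], modes=["transductive"],
            cfg=cfg, seed=SEED,
        )
        out[include] = table.iloc[0]
    return out


@pytest.fixture(scope="session")
def overlap0_setup():
    """Cohort with zero gene–disease annotation overlap: the phenotype channel
    carries no signal by construction."""
    cohort = simulate_cohort(SynthConfig(n_variants=2000, overlap=0.0))
    cfg = BenchmarkConfig().seeded(SEED)
    train, val, test = split_associations(cohort.kb.annotations.associations, cfg.split)
    channel = fit_channel("transe", cohort, train, val, cfg)
    heldout = pd.concat([val, test], ignore_index=True)
    return {"cohort": cohort, "channel": channel, "heldout": heldout}
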