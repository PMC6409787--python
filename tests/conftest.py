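"""Shared fixtures: session-scoped simulations reused across test modules.

The `standard_sim` fixture is the package's standard recovery benchmark: a
300 kb genome carrying four subfamilies at known ages, one of them partly
truncated, plus a partially sharing second genome. The `abundance_sim`
fixture is a copy-number ladder (2/5/10/20 copies) with two independent
read simulations of the same genome at 8x depth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from retrodyn.abundance import (
    MappingSummary,
    aggregate_families,
    element_rpkm,
    map_reads_single_end,
)
from retrodyn.discover import (
    classify_subfamilies,
    filter_by_domains,
    find_ltr_candidates,
)
from retrodyn.simdata import (
    SimConfig,
    SubfamilySpec,
    apply_sharing_flags,
    derive_second_genome,
    simulate_genome,
    simulate_reads,
)


def template_library(truth) -> dict[str, str]:
    """Reference library = the planting templates (full elements)."""
    return {
        name: ltr + internal + ltr
        for name, (ltr, internal) in truth.templates.items()
    }


def ltr_library(truth) -> dict[str, str]:
    return {name: ltr for name, (ltr, _) in truth.templates.items()}


STANDARD_CONFIG = SimConfig(
    genome_length=300_000,
    gc_content=0.4,
    subfamilies=(
        SubfamilySpec(name="CopiaA", superfamily="copia", copy_number=6,
                      age_my=1.0),
        SubfamilySpec(name="GypsyB", superfamily="gypsy", copy_number=5,
                      age_my=2.0),
        SubfamilySpec(name="CopiaC", superfamily="copia", copy_number=5,
                      age_my=0.5),
        SubfamilySpec(name="GypsyD", superfamily="gypsy", copy_number=6,
                      age_my=3.0, truncated_fraction=1 / 3),
    ),
    depth=8.0,
    seed=2024,
)


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict[str, str]
    truth: object
    genome_b: dict[str, str] | None = None
    truth_b: object | None = None


@pytest.fixture(scope="session")
def standard_sim() -> SimBundle:
    genome, truth = simulate_genome(STANDARD_CONFIG)
    genome_b, truth_b = derive_second_genome(
        genome, truth, shared_fraction=0.5, seed=77, extra_specific=3
    )
    apply_sharing_flags(truth, truth_b)
    return SimBundle(STANDARD_CONFIG, genome, truth, genome_b, truth_b)


@dataclass
class DiscoveryBundle:
    candidates: list
    elements: list
    assignments: list


@pytest.fixture(scope="session")
def standard_discovery(standard_sim) -> DiscoveryBundle:
    candidates = find_ltr_candidates(standard_sim.genome)
    elements = filter_by_domains(candidates, standard_sim.genome)
    assignments = classify_subfamilies(
        elements, template_library(standard_sim.truth)
    )
    return DiscoveryBundle(candidates, elements, assignments)


LADDER_COPIES = {"FamW": 2, "FamX": 5, "FamY": 10, "FamZ": 20}

LADDER_CONFIG = SimConfig(
    genome_length=300_000,
    subfamilies=tuple(
        SubfamilySpec(name=name, superfamily="copia" if i % 2 else "gypsy",
                      ltr_length=300, internal_length=2400,
                      copy_number=cn, age_my=0.5)
        for i, (name, cn) in enumerate(sorted(LADDER_COPIES.items()))
    ),
    depth=8.0,
    read_length=100,
    error_rate=0.001,
    seed=91,
)


@dataclass
class AbundanceBundle:
    config: SimConfig
    genome: dict[str, str]
    truth: object
    family_tables: "object"       # families x replicates DataFrame
    n_genome: dict[str, int]


@pytest.fixture(scope="session")
def abundance_sim() -> AbundanceBundle:
    import dataclasses

    import pandas as pd

    genome, truth = simulate_genome(LADDER_CONFIG)
    # elements and families straight from truth (isolates the abundance
    # stage from detector behaviour)
    el_seqs = {
        r.copy_id: genome[r.contig][r.start : r.end] for r in truth.records
    }
    lengths = {k: len(v) for k, v in el_seqs.items()}

    @dataclasses.dataclass(frozen=True)
    class TruthAssignment:
        element_id: str
        subfamily: str
        status: str = "classified"

    assignments = [
        TruthAssignment(r.copy_id, r.subfamily) for r in truth.records
    ]
    fam_cols = {}
    n_genome_by_rep = {}
    for ri, rep_seed in enumerate((1001, 1002)):
        rcfg = dataclasses.replace(LADDER_CONFIG, seed=rep_seed)
        pairs = simulate_reads(genome, rcfg)
        mates = {
            "mate1": [(pid, r1) for pid, r1, _ in pairs],
            "mate2": [(pid, r2) for pid, _, r2 in pairs],
        }
        summaries: dict[str, MappingSummary] = {}
        n_genome = 0
        for mi, (mate, reads) in enumerate(mates.items()):
            gsum = map_reads_single_end(
                reads, genome, seed=500 + 10 * ri + mi, mate=mate
            )
            summaries[mate] = map_reads_single_end(
                reads, el_seqs, seed=600 + 10 * ri + mi, mate=mate
            )
            n_genome += gsum.n_mapped
        el = element_rpkm(summaries["mate1"], summaries["mate2"], lengths,
                          n_genome)
        rep = f"rep{ri + 1}"
        fam_cols[rep] = aggregate_families(el, assignments)
        n_genome_by_rep[rep] = n_genome
    return AbundanceBundle(
        LADDER_CONFIG, genome, truth, pd.DataFrame(fam_cols), n_genome_by_rep
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
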