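"""End-to-end orchestration: simulate -> discover -> abundance -> date ->
landscape -> lineage, from one declarative config, with derived per-stage
seeds and a consolidated report.

The report aggregates the same tables the individual stages export — a
mapping summary (reads processed / genome-mapped / element-mapped / ratio),
family RPKM totals with the high-copy share, the insertion-age histogram,
per-window locus counts and the homologous/specific site summary — and every
number in it is recomputable from the stage TSVs. Reruns with the same
config are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from ._seq import derive_seed
from .abundance import (
    aggregate_families,
    compare_accessions,
    element_rpkm,
    map_reads_single_end,
    select_high_copy,
)
from .dating import ClockConfig, age_histogram, date_elements
from .discover import (
    DetectorParams,
    classify_subfamilies,
    filter_by_domains,
    find_ltr_candidates,
)
from .landscape import (
    classify_sites,
    locate_ltr_copies,
    make_site_calls,
    window_counts,
)
from .lineage import cluster_lineages, extract_rt_peptide
from .simdata import (
    SimConfig,
    SubfamilySpec,
    apply_sharing_flags,
    derive_second_genome,
    simulate_genome,
    simulate_reads,
)

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed summary tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """One declarative description of a full run.

    Either ``simulate`` is present (synthetic mode: the genome, a partially
    sharing second genome and per-accession read sets are generated) or
    ``genome_fasta``/``reads`` paths are given.
    """

    output_dir: str = "retrodyn_out"
    seed: int = 0
    simulate: SimConfig | None = None
    n_accessions: int = 2
    shared_fraction: float = 0.6
    extra_specific_b: int = 4
    genome_fasta: str | None = None
    genome_b_fasta: str | None = None
    reads: dict[str, tuple[str, str]] = field(default_factory=dict)
    library_fasta: str | None = None
    detector: DetectorParams = field(default_factory=DetectorParams)
    clock: ClockConfig = field(default_factory=ClockConfig)
    max_mismatch: int = 2
    min_identity: float = 70.0
    top_n: int = 10
    log2_threshold: float = 2.0
    window: int = 1_000_000
    flank: int = 200
    flank_identity: float = 80.0

    def validate(self) -> None:
        if self.simulate is None:
            if self.genome_fasta is None or not self.reads:
                raise ValueError(
                    "config needs either a simulate block or both a genome "
                    "FASTA and read files"
                )

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = _to_jsonable(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        subs = tuple(
            SubfamilySpec(**{**s, "age_my": _age(s.get("age_my", 1.0))})
            for s in sim.pop("subfamilies", [])
        )
        sim = SimConfig(subfamilies=subs, **sim)
    det = DetectorParams(**raw.pop("detector", {}))
    clock = ClockConfig(**raw.pop("clock", {}))
    return PipelineConfig(simulate=sim, detector=det, clock=clock, **raw)


def _age(a):
    return tuple(a) if isinstance(a, list) else a


def make_mapping_summary(stats: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Reads processed / genome-mapped / element-mapped per accession.

    ``stats[accession]`` holds reads_processed, genome_mapped and
    element_mapped read counts. Percentages use half-up rounding to one
    decimal; the element/genome ratio is reported as a percentage.
    """
    rows = {}
    for acc in stats:
        s = stats[acc]
        genome_pct = (
            round_half_up(100.0 * s["genome_mapped"] / s["reads_processed"])
            if s["reads_processed"] else float("nan")
        )
        ratio = (
            round_half_up(100.0 * s["element_mapped"] / s["genome_mapped"])
            if s["genome_mapped"] else float("nan")
        )
        rows[acc] = {
            "reads_processed": s["reads_processed"],
            "genome_mapped": s["genome_mapped"],
            "genome_mapped_pct": genome_pct,
            "element_mapped": s["element_mapped"],
            "element_to_genome_pct": ratio,
        }
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write a consolidated report bundle.

    Returns the report dict (also written as JSON to the output directory).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # ---- stage 1: inputs -------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate is not None:
            simcfg = dataclasses.replace(
                config.simulate, seed=derive_seed(config.seed, 101)
            )
            genome, truth = simulate_genome(simcfg)
            genome_b, truth_b = derive_second_genome(
                genome, truth, config.shared_fraction,
                seed=derive_seed(config.seed, 102),
                extra_specific=config.extra_specific_b,
            )
            apply_sharing_flags(truth, truth_b)
            library = {
                name: ltr + internal + ltr
                for name, (ltr, internal) in truth.templates.items()
            }
            accession_reads = {}
            for i in range(config.n_accessions):
                rcfg = dataclasses.replace(
                    simcfg, seed=derive_seed(config.seed, 103, i)
                )
                accession_reads[f"acc{i + 1}"] = simulate_reads(genome, rcfg)
            rio.write_fasta(genome, out / "genome_a.fasta")
            rio.write_fasta(genome_b, out / "genome_b.fasta")
            rio.write_truth(truth, out / "truth_a.tsv", out / "truth_a.bed")
            rio.write_truth(truth_b, out / "truth_b.tsv", out / "truth_b.bed")
            for acc, pairs in accession_reads.items():
                rio.write_fastq_pairs(
                    pairs, out / f"{acc}_1.fastq", out / f"{acc}_2.fastq"
                )
        else:
            genome = rio.read_fasta(config.genome_fasta)
            genome_b = (rio.read_fasta(config.genome_b_fasta)
                        if config.genome_b_fasta else None)
            library = (rio.read_fasta(config.library_fasta)
                       if config.library_fasta else None)
            accession_reads = {
                acc: _pair_reads(rio.read_fastq(p1), rio.read_fastq(p2))
                for acc, (p1, p2) in config.reads.items()
            }
            truth = None

        # ---- stage 2: discover -------------------------------------------
        stage = "discover"
        candidates = find_ltr_candidates(genome, config.detector)
        elements = filter_by_domains(candidates, genome)
        if library is None:
            raise ValueError("no reference library available for classification")
        assignments = classify_subfamilies(
            elements, library, min_identity=config.min_identity
        )
        rio.write_tsv(rio.candidates_to_frame(candidates),
                      out / "candidates.tsv", index=False)
        rio.write_tsv(rio.candidates_to_frame(elements),
                      out / "elements.tsv", index=False)
        rio.write_tsv(pd.DataFrame([vars(a) for a in assignments]),
                      out / "assignments.tsv", index=False)
        classified = {a.element_id for a in assignments
                      if a.status == "classified"}
        report["n_candidates"] = len(candidates)
        report["n_elements"] = len(elements)
        report["n_classified"] = len(classified)

        # ---- stage 3: abundance ------------------------------------------
        stage = "abundance"
        el_seqs = {e.id: e.sequence for e in elements
                   if e.id in classified}
        lengths = {eid: len(s) for eid, s in el_seqs.items()}
        fam_cols = {}
        map_stats = {}
        for ai, (acc, pairs) in enumerate(sorted(accession_reads.items())):
            mates = {
                "mate1": [(pid, r1) for pid, r1, _ in pairs],
                "mate2": [(pid, r2) for pid, _, r2 in pairs],
            }
            summaries = {}
            n_genome = 0
            n_element = 0
            for mi, (mate, reads) in enumerate(mates.items()):
                gsum = map_reads_single_end(
                    reads, genome, config.max_mismatch,
                    seed=derive_seed(config.seed, 201, ai, mi),
                    accession=acc, mate=mate,
                )
                esum = map_reads_single_end(
                    reads, el_seqs, config.max_mismatch,
                    seed=derive_seed(config.seed, 202, ai, mi),
                    accession=acc, mate=mate,
                )
                summaries[mate] = esum
                n_genome += gsum.n_mapped
                n_element += esum.n_mapped
            el_rpkm = element_rpkm(
                summaries["mate1"], summaries["mate2"], lengths, n_genome
            )
            fam_cols[acc] = aggregate_families(el_rpkm, assignments)
            map_stats[acc] = {
                "reads_processed": 2 * len(pairs),
                "genome_mapped": n_genome,
                "element_mapped": n_element,
            }
        family_tables = pd.DataFrame(fam_cols).fillna(0.0)
        high_copy = select_high_copy(family_tables, config.top_n)
        comparisons = compare_accessions(family_tables, config.log2_threshold)
        mapping_summary = make_mapping_summary(map_stats)
        rio.write_tsv(family_tables, out / "family_rpkm.tsv")
        rio.write_tsv(mapping_summary, out / "mapping_summary.tsv")
        rio.write_tsv(pd.DataFrame([vars(c) for c in comparisons]),
                      out / "comparisons.tsv", index=False)
        totals = family_tables.sum(axis=0)
        high_totals = family_tables.loc[
            family_tables.index.isin(high_copy)].sum(axis=0)
        report["mapping_summary"] = mapping_summary.to_dict("index")
        report["high_copy_families"] = high_copy
        report["family_rpkm_totals"] = {
            acc: round_half_up(v, 1) for acc, v in totals.items()}
        report["high_copy_pct"] = {
            acc: round_half_up(100.0 * high_totals[acc] / totals[acc])
            if totals[acc] else 0.0
            for acc in family_tables.columns
        }
        report["n_flagged_comparisons"] = sum(c.flagged for c in comparisons)

        # ---- stage 4: dating ---------------------------------------------
        stage = "dating"
        dated = date_elements(
            [e for e in elements if e.id in classified], genome, config.clock
        )
        rio.write_tsv(
            pd.DataFrame(
                [{"element_id": d.element_id, "columns": d.aligned_columns,
                  "k": d.k, "t_years": d.t_years, "t_my": d.t_my}
                 for d in dated]
            ),
            out / "ages.tsv", index=False,
        )
        if dated:
            hist = age_histogram(dated)
            rio.write_tsv(
                pd.DataFrame({
                    "bin_start_my": [i * hist.bin_width_years / 1e6
                                     for i in range(len(hist.counts))],
                    "count": hist.counts,
                }),
                out / "age_histogram.tsv", index=False,
            )
            report["age_mean_my"] = round(hist.mean_my, 3)
            report["age_max_my"] = round(hist.max_my, 3)
            report["age_frac_le_10my"] = round(hist.frac_le_10my, 4)
            report["age_frac_first_bin"] = round(hist.frac_first_bin, 4)

        # ---- stage 5: landscape --------------------------------------------
        stage = "landscape"
        ltr_lib = {
            name: ltr for name, (ltr, _) in truth.templates.items()
        } if truth is not None else {
            e.id: genome[e.contig][e.ltr5_start:e.ltr5_end] for e in elements
        }
        loci_a = locate_ltr_copies(ltr_lib, genome, "A")
        contig_lengths = {c: len(s) for c, s in genome.items()}
        wins = window_counts(loci_a, contig_lengths, config.window)
        rio.write_tsv(rio.loci_to_bed(loci_a), out / "loci_a.bed", index=False)
        rio.write_tsv(pd.DataFrame([vars(w) for w in wins]),
                      out / "window_counts.tsv", index=False)
        report["n_loci_a"] = len(loci_a)
        if genome_b is not None:
            loci_b = locate_ltr_copies(ltr_lib, genome_b, "B")
            calls_a = make_site_calls(loci_a, genome, config.flank)
            calls_b = make_site_calls(loci_b, genome_b, config.flank)
            _, site_summary = classify_sites(
                calls_a, calls_b, config.flank_identity
            )
            rio.write_tsv(site_summary, out / "site_summary.tsv")
            report["n_loci_b"] = len(loci_b)
            report["site_summary"] = {
                str(k): {c: int(v) for c, v in row.items()}
                for k, row in site_summary.to_dict("index").items()
            }

        # ---- stage 6: lineage ----------------------------------------------
        stage = "lineage"
        high_ids = {
            a.element_id for a in assignments
            if a.status == "classified" and a.subfamily in set(high_copy)
        }
        rt_elements = [
            e for e in elements
            if e.id in high_ids and e.superfamily in ("copia", "gypsy")
            and any(d.startswith("RT_") for d in e.domains_found)
        ]
        if rt_elements:
            peptides = [extract_rt_peptide(e) for e in rt_elements]
            lineage_calls = cluster_lineages(peptides)
            rio.write_tsv(
                pd.DataFrame(
                    [{"element_id": eid, "lineage": lin, "ambiguous": amb}
                     for eid, (lin, amb) in sorted(lineage_calls.items())]
                ),
                out / "lineages.tsv", index=False,
            )
            report["lineage_calls"] = {
                eid: lin for eid, (lin, _) in sorted(lineage_calls.items())
            }
    except Exception:
        log.error("pipeline failed in stage %r; partial outputs kept in %s",
                  stage, out)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _pair_reads(mate1, mate2):
    return [(id1.rstrip("/1"), s1, s2)
            for (id1, s1), (_, s2) in zip(mate1, mate2)]
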