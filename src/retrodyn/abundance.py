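"""Read-depth relative copy numbers of LTR-RT subfamilies.

Reads are mapped ungapped, end-to-end, with at most ``max_mismatch``
substitutions (a Bowtie-1-like contract), each mate file as an independent
single-end pass. Per-element abundance is expressed as

    RPKM = c * 1e8 / (L * N)

reads mapped to the element (c) per kilobase of element (L, in bases — the
1e8 constant absorbs the kb conversion) per hundred thousand reads mapped to
the reference genome (N). The element value is the mean of the two mate
passes; family abundance is the sum over the family's classified members.
Accessions are compared family-by-family on |log2 ratio|, with >= 2 (a
four-fold difference) flagged as significant.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, pack_kmers, revcomp_codes

log = logging.getLogger(__name__)


@dataclass
class MappingSummary:
    """Per-target mapped-read counts for one accession / one mate pass."""

    accession: str
    mate: str                      # "mate1" | "mate2"
    counts: dict[str, int]         # target name -> mapped reads
    n_reads: int                   # reads processed
    n_mapped: int                  # reads mapped (== sum of counts)

    @property
    def total_counts(self) -> int:
        return sum(self.counts.values())


@dataclass
class RpkmTable:
    """Per-element and per-family RPKM for one accession."""

    accession: str
    element_rpkm: pd.Series        # index: element id
    family_rpkm: pd.Series         # index: family name
    element_lengths: pd.Series
    n_genome_mapped: int


@dataclass(frozen=True)
class ComparisonRecord:
    family: str
    accession_a: str
    accession_b: str
    log2_ratio: float
    flagged: bool


class ReadMapper:
    """Exact-substring-seeded ungapped mapper over a fixed target set.

    Pigeonhole seeding: a read with at most ``max_mismatch`` mismatches must
    contain at least one exact seed of length ``len(read) // (max_mismatch+1)``
    at one of the seed offsets, so lookups of those seeds followed by
    full-length Hamming verification find every valid alignment.
    """

    def __init__(self, targets: dict[str, str], max_mismatch: int = 2,
                 seed_len: int | None = None, read_length_hint: int = 100):
        self.max_mismatch = max_mismatch
        self.names = sorted(targets)
        self.codes = [encode(targets[n].upper()) for n in self.names]
        self.k = seed_len or max(10, read_length_hint // (max_mismatch + 1))
        self.index: dict[int, list[tuple[int, int]]] = {}
        for t, codes in enumerate(self.codes):
            for pos, km in enumerate(pack_kmers(codes, self.k)):
                self.index.setdefault(int(km), []).append((t, pos))

    def _candidates(self, read: np.ndarray):
        """(target, start) candidate placements from pigeonhole seeds."""
        L = len(read)
        n_seeds = self.max_mismatch + 1
        offsets = [i * self.k for i in range(n_seeds) if i * self.k + self.k <= L]
        kms = pack_kmers(read, self.k)
        seen = set()
        for off in offsets:
            for t, pos in self.index.get(int(kms[off]), ()):
                start = pos - off
                if start >= 0 and start + L <= len(self.codes[t]):
                    seen.add((t, start))
        return seen

    def map_read(self, read: np.ndarray) -> list[tuple[int, int, int]]:
        """All best placements: (target_idx, start, strand) at min mismatches."""
        best = self.max_mismatch + 1
        hits: list[tuple[int, int, int]] = []
        for strand, r in ((0, read), (1, revcomp_codes(read))):
            for t, start in sorted(self._candidates(r)):
                mm = int(np.count_nonzero(
                    self.codes[t][start : start + len(r)] != r))
                if mm < best:
                    best = mm
                    hits = [(t, start, strand)]
                elif mm == best and mm <= self.max_mismatch:
                    hits.append((t, start, strand))
        return hits if best <= self.max_mismatch else []


def map_reads_single_end(
    reads: list[tuple[str, str]],
    targets: dict[str, str],
    max_mismatch: int = 2,
    seed: int = 0,
    accession: str = "sample",
    mate: str = "mate1",
) -> MappingSummary:
    """Count reads per target; multi-mapping ties broken uniformly at random.

    ``reads`` are (id, sequence) pairs. Each mapped read increments exactly
    one target, so the total increments equal the number of mapped reads.
    """
    if not reads:
        raise ValueError("no reads supplied")
    lens = {len(s) for _, s in reads}
    mapper = ReadMapper(targets, max_mismatch,
                        read_length_hint=min(lens))
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in mapper.names}
    n_mapped = 0
    n_too_long = 0
    max_target = max(len(c) for c in mapper.codes)
    for _, seq in reads:
        if len(seq) > max_target:
            n_too_long += 1
            continue
        hits = mapper.map_read(encode(seq.upper()))
        if not hits:
            continue
        t, _, _ = hits[int(rng.integers(len(hits)))] if len(hits) > 1 else hits[0]
        counts[mapper.names[t]] += 1
        n_mapped += 1
    if n_too_long:
        log.warning("%d reads longer than every target; counted unmapped",
                    n_too_long)
    return MappingSummary(accession, mate, counts, len(reads), n_mapped)


def compute_rpkm(c: float, length: int, n_genome: int) -> float:
    """RPKM = c * 1e8 / (L * N); L in bases, N genome-mapped reads."""
    if length <= 0:
        raise ValueError("element length must be > 0")
    if n_genome <= 0:
        raise ZeroDivisionError(
            "no genome-mapped reads (N = 0); RPKM undefined"
        )
    return c * 1e8 / (length * n_genome)


def element_rpkm(
    mate1: MappingSummary,
    mate2: MappingSummary,
    lengths: dict[str, int],
    n_genome: int,
) -> pd.Series:
    """Per-element RPKM: mean of the two single-end mate passes."""
    out = {}
    for name in sorted(lengths):
        r1 = compute_rpkm(mate1.counts.get(name, 0), lengths[name], n_genome)
        r2 = compute_rpkm(mate2.counts.get(name, 0), lengths[name], n_genome)
        out[name] = (r1 + r2) / 2.0
    return pd.Series(out, name=mate1.accession)


def aggregate_families(
    element_rpkm: pd.Series, assignments
) -> pd.Series:
    """Family RPKM = sum of classified member-element RPKM values."""
    fam_of = {
        a.element_id: a.subfamily
        for a in assignments
        if a.status == "classified"
    }
    dropped = [e for e in element_rpkm.index if e not in fam_of]
    if dropped:
        log.info("%d elements without a classified subfamily excluded "
                 "from family totals", len(dropped))
    kept = element_rpkm[element_rpkm.index.isin(fam_of)]
    fams = kept.groupby(kept.index.map(fam_of)).sum()
    fams.name = element_rpkm.name
    return fams.sort_index()


def select_high_copy(
    family_tables: pd.DataFrame, top_n: int = 10
) -> list[str]:
    """Union of each accession's top-``top_n`` families by RPKM.

    ``family_tables``: rows = families, columns = accessions. Rank ties at
    the cutoff are broken by family name so the set is deterministic.
    """
    chosen: set[str] = set()
    for acc in family_tables.columns:
        col = family_tables[acc]
        if len(col) < top_n:
            log.warning("accession %s has only %d families (< top_n=%d)",
                        acc, len(col), top_n)
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        chosen.update(name for name, _ in ranked[:top_n])
    return sorted(chosen)


def compare_accessions(
    family_tables: pd.DataFrame,
    threshold: float = 2.0,
    zero_floor: float = 0.1,
) -> list[ComparisonRecord]:
    """Pairwise |log2 ratio| comparison of family RPKM between accessions.

    Zero handling: both values zero -> ratio 0, not flagged; exactly one
    zero -> ratio recorded as +/-inf, flagged only when the nonzero value is
    at least ``zero_floor``.
    """
    records: list[ComparisonRecord] = []
    cols = list(family_tables.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            for fam in family_tables.index:
                va, vb = family_tables.at[fam, a], family_tables.at[fam, b]
                if va == 0 and vb == 0:
                    ratio, flagged = 0.0, False
                elif va == 0 or vb == 0:
                    ratio = math.inf if vb == 0 else -math.inf
                    flagged = max(va, vb) >= zero_floor
                else:
                    ratio = math.log2(va / vb)
                    flagged = abs(ratio) >= threshold
                records.append(ComparisonRecord(fam, a, b, ratio, flagged))
    return records


def flagged_fraction_pct(records: list[ComparisonRecord],
                         accession_a: str, accession_b: str) -> float:
    """Percentage of families flagged in one accession pair, 1 decimal."""
    pair = [r for r in records
            if {r.accession_a, r.accession_b} == {accession_a, accession_b}]
    if not pair:
        return 0.0
    return round(100.0 * sum(r.flagged for r in pair) / len(pair), 1)
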