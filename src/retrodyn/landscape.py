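"""Chromosomal distribution and cross-genome insertion-site comparison.

LTR query sequences are located on one or two genomes by seeded ungapped
search; loci are binned into fixed non-overlapping windows (1 Mb by default)
for distribution profiles, and each locus's +/-200 bp flanks are compared
across genomes to call an insertion site homologous (same flank context in
both genomes, i.e. an insertion predating the split) or genome-specific.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, pack_kmers, revcomp_codes
from .align import pairwise_nuc_stats

log = logging.getLogger(__name__)


@dataclass
class LtrLocus:
    query: str           # LTR / subfamily label of the searched sequence
    genome: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float      # percent


@dataclass
class SiteCall:
    locus: LtrLocus
    upstream: str
    downstream: str
    short_flank: bool
    status: str = "specific"            # "homologous" | "specific"
    matched: str | None = None          # id of the matched locus, if any

    @property
    def site_id(self) -> str:
        loc = self.locus
        return f"{loc.genome}:{loc.contig}:{loc.start}-{loc.end}:{loc.query}"


@dataclass(frozen=True)
class WindowCount:
    contig: str
    window_index: int
    window_start: int
    window_end: int
    count: int


def locate_ltr_copies(
    ltr_library: dict[str, str],
    genome: dict[str, str],
    genome_id: str = "A",
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
    k: int = 16,
    max_kmer_occ: int = 2000,
) -> list[LtrLocus]:
    """Find all copies of each query LTR in the genome (both strands).

    Seeded ungapped search: shared k-mers between query and contig define
    candidate diagonals; each diagonal supporting >= 2 anchors is evaluated
    by placing the full query at that offset and scoring identity over the
    overlap. Overlapping hits from the same query keep the best-identity one.
    """
    out: list[LtrLocus] = []
    for contig in sorted(genome):
        cseq = genome[contig].upper()
        codes = encode(cseq)
        if len(codes) < k:
            continue
        index: dict[int, list[int]] = {}
        for pos, km in enumerate(pack_kmers(codes, k)):
            index.setdefault(int(km), []).append(pos)
        for qname in sorted(ltr_library):
            qcodes_f = encode(ltr_library[qname].upper())
            hits: list[LtrLocus] = []
            for strand, q in (("+", qcodes_f), ("-", revcomp_codes(qcodes_f))):
                diags: dict[int, int] = {}
                for qpos, km in enumerate(pack_kmers(q, k)):
                    entries = index.get(int(km), ())
                    if len(entries) > max_kmer_occ:
                        continue
                    for cpos in entries:
                        dkey = cpos - qpos
                        diags[dkey] = diags.get(dkey, 0) + 1
                for d, support in sorted(diags.items()):
                    if support < 2:
                        continue
                    lo = max(0, d)
                    hi = min(len(codes), d + len(q))
                    span = hi - lo
                    if span < min_coverage * len(q):
                        continue
                    m = codes[lo:hi] == q[lo - d : hi - d]
                    ident = 100.0 * np.count_nonzero(m) / span
                    if ident < min_identity:
                        continue
                    hits.append(
                        LtrLocus(qname, genome_id, contig, lo, hi, strand,
                                 float(ident))
                    )
            out.extend(_merge_query_hits(hits))
    out.sort(key=lambda l: (l.contig, l.start, l.query))
    return out


def _merge_query_hits(hits: list[LtrLocus]) -> list[LtrLocus]:
    """Keep the best-identity hit among overlapping hits of one query."""
    kept: list[LtrLocus] = []
    for h in sorted(hits, key=lambda l: (-l.identity, -(l.end - l.start),
                                         l.start)):
        if all(h.end <= o.start or o.end <= h.start for o in kept):
            kept.append(h)
    kept.sort(key=lambda l: l.start)
    return kept


def window_counts(
    loci: list[LtrLocus],
    contig_lengths: dict[str, int],
    window: int = 1_000_000,
) -> list[WindowCount]:
    """Count loci per non-overlapping window; a locus belongs to the window
    containing its start coordinate. The final partial window is kept."""
    out: list[WindowCount] = []
    per_contig: dict[str, list[int]] = {c: [] for c in contig_lengths}
    for loc in loci:
        per_contig.setdefault(loc.contig, []).append(loc.start)
    for contig in sorted(contig_lengths):
        clen = contig_lengths[contig]
        n_win = max(1, -(-clen // window))
        counts = np.zeros(n_win, dtype=int)
        for s in per_contig.get(contig, []):
            counts[min(s // window, n_win - 1)] += 1
        for w in range(n_win):
            out.append(
                WindowCount(contig, w, w * window,
                            min((w + 1) * window, clen), int(counts[w]))
            )
    return out


def extract_flanks(
    genome: dict[str, str], locus: LtrLocus, flank: int = 200
) -> tuple[str, str, bool]:
    """(upstream, downstream, short_flag) around a locus.

    Flanks are reported in genome forward orientation regardless of the
    locus strand; they are truncated (and flagged) at contig edges.
    """
    seq = genome[locus.contig]
    if not (0 <= locus.start <= locus.end <= len(seq)):
        raise ValueError(f"locus {locus} outside contig bounds")
    up = seq[max(0, locus.start - flank) : locus.start]
    down = seq[locus.end : locus.end + flank]
    return up, down, len(up) < flank or len(down) < flank


def make_site_calls(
    loci: list[LtrLocus], genome: dict[str, str], flank: int = 200
) -> list[SiteCall]:
    return [
        SiteCall(loc, *extract_flanks(genome, loc, flank)) for loc in loci
    ]


def _flanks_match(a: SiteCall, b: SiteCall, min_identity: float,
                  min_len: int) -> float | None:
    """Mean flank identity if both flank pairs match, else None."""
    idents = []
    for fa, fb in ((a.upstream, b.upstream), (a.downstream, b.downstream)):
        if min(len(fa), len(fb)) < min_len:
            return None
        st = pairwise_nuc_stats(fa, fb)
        if st.ungapped_columns < min_len:
            return None
        ident = 100.0 * st.matches / st.ungapped_columns
        if ident < min_identity:
            return None
        idents.append(ident)
    return sum(idents) / 2.0


def classify_sites(
    calls_a: list[SiteCall],
    calls_b: list[SiteCall],
    min_flank_identity: float = 80.0,
    min_flank_len: int = 100,
) -> tuple[list[SiteCall], pd.DataFrame]:
    """Label sites homologous/specific by mutual one-to-one flank matching.

    A site in genome A is homologous iff some same-query site in genome B has
    both flanks matching at >= ``min_flank_identity`` % identity over
    >= ``min_flank_len`` aligned bases; matching is greedy by identity with
    deterministic ordering, and one-to-one. Returns the annotated calls of
    both genomes plus a per-subfamily summary table.
    """
    for c in calls_a + calls_b:
        c.status, c.matched = "specific", None
    by_query_b: dict[str, list[SiteCall]] = {}
    for c in calls_b:
        by_query_b.setdefault(c.locus.query, []).append(c)

    scored: list[tuple[float, SiteCall, SiteCall]] = []
    for ca in calls_a:
        for cb in by_query_b.get(ca.locus.query, ()):
            ident = _flanks_match(ca, cb, min_flank_identity, min_flank_len)
            if ident is not None:
                scored.append((ident, ca, cb))
    scored.sort(key=lambda t: (-t[0], t[1].site_id, t[2].site_id))
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    for ident, ca, cb in scored:
        if ca.site_id in taken_a or cb.site_id in taken_b:
            continue
        taken_a.add(ca.site_id)
        taken_b.add(cb.site_id)
        ca.status = cb.status = "homologous"
        ca.matched, cb.matched = cb.site_id, ca.site_id

    rows = []
    queries = sorted({c.locus.query for c in calls_a + calls_b})
    for q in queries:
        qa = [c for c in calls_a if c.locus.query == q]
        qb = [c for c in calls_b if c.locus.query == q]
        rows.append({
            "subfamily": q,
            "mapped_a": len(qa),
            "specific_a": sum(c.status == "specific" for c in qa),
            "mapped_b": len(qb),
            "specific_b": sum(c.status == "specific" for c in qb),
        })
    summary = pd.DataFrame(rows).set_index("subfamily")
    summary.loc["Total"] = summary.sum()
    return calls_a + calls_b, summary
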