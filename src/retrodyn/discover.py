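"""Structural discovery, domain filtering and library classification of
full-length LTR retrotransposons.

The detector finds pairs of same-orientation repeats (the two LTRs) by exact
k-mer self-anchoring: repeated k-mers at a genomic separation compatible with
an element are grouped by diagonal, chained, extended ungapped with an X-drop
rule, and the resulting repeat pair is scored by a global LTR-LTR alignment.
Survivors are screened for protein-coding evidence (GAG / integrase / RT
profiles over all six reading frames) and finally classified against a
reference retroelement library by identity and reference coverage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import encode, pack_kmers, revcomp_codes
from .align import pairwise_nuc_stats
from .profiles import (
    DomainProfile,
    GAG,
    INT,
    RT_COPIA,
    RT_GYPSY,
    best_six_frame_score,
    default_profiles,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Structural-search settings (lengths in bases, similarity in percent)."""

    min_ltr_len: int = 100
    max_ltr_len: int = 2000
    min_element_len: int = 1000
    max_element_len: int = 16000
    min_ltr_similarity: float = 85.0
    k: int = 20             # anchor k-mer size
    max_kmer_occ: int = 100  # skip k-mers more frequent than this
    min_anchors: int = 2
    chain_gap: int = 300     # max spacing between chained anchors
    diag_merge: int = 15     # merge clusters this close in diagonal
    xdrop: int = 12
    tsd_range: tuple[int, int] = (4, 6)


@dataclass
class LTRCandidate:
    """A structurally detected candidate element (0-based, half-open)."""

    id: str
    contig: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_similarity: float
    tsd: str | None = None
    termini_motif: bool = False


@dataclass
class LTRElement(LTRCandidate):
    """A candidate that survived the protein-domain filter."""

    domains_found: frozenset[str] = frozenset()
    superfamily: str = "unknown"
    sequence: str = ""


@dataclass(frozen=True)
class SubfamilyAssignment:
    element_id: str
    subfamily: str | None
    identity: float      # percent identity of the best hit
    coverage: float      # fraction of the best reference covered
    status: str          # classified | partial_hit | multi_hit | no_hit


def _anchor_clusters(codes: np.ndarray, params: DetectorParams):
    """Yield (diagonal, i_min, i_max) clusters of repeated k-mer anchors."""
    k = params.k
    n = len(codes)
    if n < params.min_element_len or n < k:
        return []
    kmers = pack_kmers(codes, k)
    order = np.argsort(kmers, kind="stable")
    sk = kmers[order]
    boundaries = np.nonzero(np.diff(sk))[0] + 1
    groups = np.split(order, boundaries)

    d_min = max(params.min_element_len - params.max_ltr_len, params.min_ltr_len)
    d_max = params.max_element_len

    anchors: dict[int, list[int]] = {}
    for g in groups:
        if len(g) < 2 or len(g) > params.max_kmer_occ:
            continue
        pos = np.sort(g)
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                d = int(pos[b] - pos[a])
                if d_min <= d <= d_max:
                    anchors.setdefault(d, []).append(int(pos[a]))

    clusters = []
    for d in sorted(anchors):
        starts = sorted(anchors[d])
        run = [starts[0]]
        for p in starts[1:]:
            if p - run[-1] <= params.chain_gap:
                run.append(p)
            else:
                if len(run) >= params.min_anchors:
                    clusters.append((d, run[0], run[-1] + params.k))
                run = [p]
        if len(run) >= params.min_anchors:
            clusters.append((d, run[0], run[-1] + params.k))

    # merge clusters on nearby diagonals covering the same left-copy interval
    merged: list[tuple[int, int, int]] = []
    for d, lo, hi in sorted(clusters):
        for idx, (d2, lo2, hi2) in enumerate(merged):
            if abs(d - d2) <= params.diag_merge and lo <= hi2 and lo2 <= hi:
                if hi - lo > hi2 - lo2:  # keep the better-supported diagonal
                    merged[idx] = (d, min(lo, lo2), max(hi, hi2))
                break
        else:
            merged.append((d, lo, hi))
    return merged


def _xdrop_extend(codes: np.ndarray, d: int, lo: int, hi: int, xdrop: int):
    """Extend an ungapped repeat seed on diagonal ``d`` in both directions."""
    n = len(codes)
    # extend left from lo-1
    best = score = 0
    best_i = lo
    i = lo - 1
    while i >= 0 and i + d < n and best - score <= xdrop:
        score += 1 if codes[i] == codes[i + d] else -1
        if score > best:
            best, best_i = score, i
        i -= 1
    left = best_i
    # extend right from hi
    best = score = 0
    best_j = hi
    j = hi
    while j + d < n and best - score <= xdrop:
        score += 1 if codes[j] == codes[j + d] else -1
        if score > best:
            best, best_j = score, j + 1
        j += 1
    right = best_j
    return left, right


def _refine_termini(seq: str, d: int, left: int, right: int, window: int = 6):
    """Snap boundaries to paired TG / CA termini when present nearby."""
    start = left
    for delta in sorted(range(-window, window + 1), key=abs):
        p = left + delta
        if p >= 0 and seq[p : p + 2] == "TG" and seq[p + d : p + d + 2] == "TG":
            start = p
            break
    end = right
    for delta in sorted(range(-window, window + 1), key=abs):
        p = right + delta
        if (
            p + d <= len(seq)
            and seq[p - 2 : p] == "CA"
            and seq[p + d - 2 : p + d] == "CA"
        ):
            end = p
            break
    return start, end


def find_ltr_candidates(
    genome: dict[str, str], params: DetectorParams | None = None
) -> list[LTRCandidate]:
    """Detect candidate full-length LTR-RTs in every contig."""
    params = params or DetectorParams()
    out: list[LTRCandidate] = []
    serial = 0
    for contig in sorted(genome):
        seq = genome[contig].upper()
        if len(seq) < params.min_element_len:
            log.info("contig %s shorter than min element length; skipped", contig)
            continue
        codes = encode(seq)
        raw: list[LTRCandidate] = []
        for d, lo, hi in _anchor_clusters(codes, params):
            left, right = _xdrop_extend(codes, d, lo, hi, params.xdrop)
            left, right = _refine_termini(seq, d, left, right)
            ltr_len = right - left
            if not params.min_ltr_len <= ltr_len <= params.max_ltr_len:
                continue
            el_start, el_end = left, right + d
            el_len = el_end - el_start
            if not params.min_element_len <= el_len <= params.max_element_len:
                continue
            ltr5 = seq[left:right]
            ltr3 = seq[left + d : right + d]
            sim = pairwise_nuc_stats(ltr5, ltr3).identity_pct
            if sim < params.min_ltr_similarity:
                continue
            tsd = None
            lo_t, hi_t = params.tsd_range
            for t in sorted(range(lo_t, hi_t + 1),
                            key=lambda t: abs(t - 5)):
                if el_start - t < 0 or el_end + t > len(seq):
                    continue
                if seq[el_start - t : el_start] == seq[el_end : el_end + t]:
                    tsd = seq[el_start - t : el_start]
                    break
            motif = ltr5.startswith("TG") and ltr3.endswith("CA")
            raw.append(
                LTRCandidate(
                    id="",
                    contig=contig,
                    start=el_start,
                    end=el_end,
                    ltr5_start=left,
                    ltr5_end=right,
                    ltr3_start=left + d,
                    ltr3_end=right + d,
                    ltr_similarity=sim,
                    tsd=tsd,
                    termini_motif=motif,
                )
            )
        for cand in _resolve_overlaps(raw):
            cand.id = f"{contig}.ltr{serial}"
            serial += 1
            out.append(cand)
    return out


def _resolve_overlaps(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    """Deterministic overlap resolution.

    A target-site duplication is direct structural evidence that a repeat
    pair is a genuine insertion rather than a chance pairing of similar
    regions from two neighbouring elements, so TSD-bearing candidates win
    first; ties then go to the higher LTR similarity, then the longer span.
    """
    ranked = sorted(
        cands,
        key=lambda c: (
            c.tsd is None,
            -c.ltr_similarity,
            -(c.end - c.start),
            c.start,
        ),
    )
    kept: list[LTRCandidate] = []
    for c in ranked:
        if all(c.end <= k.start or k.end <= c.start for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def filter_by_domains(
    candidates: list[LTRCandidate],
    genome: dict[str, str],
    profiles: dict[str, DomainProfile] | None = None,
) -> list[LTRElement]:
    """Keep candidates whose internal region carries at least one domain.

    The internal region (between the two LTRs) is translated in all six
    frames and scored against every profile; a domain is called when its best
    window score reaches the profile threshold. The superfamily is set by the
    better-scoring of the two RT profiles when either passes.
    """
    profiles = profiles or default_profiles()
    needed = {GAG, INT, RT_COPIA, RT_GYPSY}
    if not needed <= set(profiles):
        raise ValueError(f"profiles must include {sorted(needed)}")
    out: list[LTRElement] = []
    for cand in candidates:
        internal = genome[cand.contig][cand.ltr5_end : cand.ltr3_start]
        found = set()
        rt_scores: dict[str, float] = {}
        for name, prof in profiles.items():
            score, _, _ = best_six_frame_score(prof, internal)
            if score >= prof.threshold:
                found.add(name)
            if name in (RT_COPIA, RT_GYPSY):
                rt_scores[name] = score
        if not found:
            continue
        if RT_COPIA in found or RT_GYPSY in found:
            superfamily = (
                "copia"
                if rt_scores.get(RT_COPIA, -np.inf)
                >= rt_scores.get(RT_GYPSY, -np.inf)
                else "gypsy"
            )
        else:
            superfamily = "unknown"
        out.append(
            LTRElement(
                **vars(cand),
                domains_found=frozenset(found),
                superfamily=superfamily,
                sequence=genome[cand.contig][cand.start : cand.end],
            )
        )
    return out


# ---------------------------------------------------------------------------
# classification against a reference library
# ---------------------------------------------------------------------------

def _diagonal_hits(q: np.ndarray, r: np.ndarray, k: int = 16):
    """Shared-k-mer diagonals between query and reference (both forward)."""
    if len(q) < k or len(r) < k:
        return {}
    qk, rk = pack_kmers(q, k), pack_kmers(r, k)
    index: dict[int, list[int]] = {}
    for pos, km in enumerate(rk):
        index.setdefault(int(km), []).append(pos)
    diags: dict[int, list[tuple[int, int]]] = {}
    for qpos, km in enumerate(qk):
        for rpos in index.get(int(km), ()):
            diags.setdefault(qpos - rpos, []).append((qpos, rpos))
    return diags


def _reference_hit(
    query: np.ndarray, ref: np.ndarray, k: int = 16, min_span_identity: float = 60.0
) -> tuple[float, float]:
    """(identity %, reference coverage fraction) of query vs one reference.

    Ungapped evaluation on every supported diagonal; coverage is the union of
    reference spans whose ungapped identity clears ``min_span_identity``.
    Suited to libraries whose members differ from queries by substitutions
    (no long indels), which is what the template-planting simulation and
    Repbase-style exemplar libraries produce.
    """
    diags = _diagonal_hits(query, ref, k)
    covered = np.zeros(len(ref), dtype=bool)
    match_at = np.zeros(len(ref), dtype=bool)
    w = 50  # sliding window for local identity along a diagonal
    for d, hits in sorted(diags.items()):
        if len(hits) < 2:
            continue
        rlo_ext = max(0, -d)
        rhi_ext = min(len(ref), len(query) - d)
        span_len = rhi_ext - rlo_ext
        if span_len < w:
            continue
        m = query[rlo_ext + d : rhi_ext + d] == ref[rlo_ext:rhi_ext]
        csum = np.concatenate([[0], np.cumsum(m)])
        frac = (csum[w:] - csum[:-w]) / w  # identity of each w-window
        hot_starts = np.nonzero(frac * 100.0 >= min_span_identity)[0]
        if len(hot_starts) == 0:
            continue
        hot = np.zeros(span_len + 1, dtype=np.int64)
        hot[hot_starts] += 1
        hot[hot_starts + w] -= 1
        hot_mask = np.cumsum(hot[:-1]) > 0
        covered[rlo_ext:rhi_ext] |= hot_mask
        match_at[rlo_ext:rhi_ext] |= hot_mask & m
    n_cov = int(covered.sum())
    coverage = n_cov / len(ref) if len(ref) else 0.0
    identity = 100.0 * match_at.sum() / n_cov if n_cov else 0.0
    return identity, float(coverage)


def classify_subfamilies(
    elements: list[LTRElement],
    library: dict[str, str],
    min_identity: float = 70.0,
    min_coverage: float = 0.8,
    min_partial_coverage: float = 0.3,
) -> list[SubfamilyAssignment]:
    """Assign each element to a reference subfamily, or flag why not.

    classified    exactly one reference covered >= ``min_coverage`` at
                  >= ``min_identity`` %, and no second reference with a
                  substantial (>= ``min_partial_coverage``) hit.
    partial_hit   one substantial hit only, below full coverage.
    multi_hit     two or more references with substantial hits (merged or
                  chimeric elements).
    no_hit        nothing above the identity/coverage floor.
    """
    if not library:
        raise ValueError("reference library is empty")
    lib_codes = {name: encode(seq.upper()) for name, seq in library.items()}
    out: list[SubfamilyAssignment] = []
    for el in elements:
        q_fwd = encode(el.sequence.upper())
        q_rev = revcomp_codes(q_fwd)
        full: list[tuple[str, float, float]] = []
        substantial: list[tuple[str, float, float]] = []
        for name in sorted(lib_codes):
            # elements are reported in genome orientation; try both strands
            hits = [_reference_hit(q, lib_codes[name]) for q in (q_fwd, q_rev)]
            ident, cov = max(hits, key=lambda t: t[0] * t[1])
            if ident >= min_identity and cov >= min_partial_coverage:
                substantial.append((name, ident, cov))
                if cov >= min_coverage:
                    full.append((name, ident, cov))
        if len(full) == 1 and len(substantial) == 1:
            name, ident, cov = full[0]
            out.append(SubfamilyAssignment(el.id, name, ident, cov, "classified"))
        elif len(substantial) >= 2:
            best = max(substantial, key=lambda t: t[1] * t[2])
            out.append(
                SubfamilyAssignment(el.id, None, best[1], best[2], "multi_hit")
            )
        elif len(substantial) == 1:
            name, ident, cov = substantial[0]
            out.append(
                SubfamilyAssignment(el.id, None, ident, cov, "partial_hit")
            )
        else:
            out.append(SubfamilyAssignment(el.id, None, 0.0, 0.0, "no_hit"))
    return out
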