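"""Synthetic genomes with planted LTR retrotransposons, paired-end reads and
a partially sharing second genome, with full ground truth.

The generator emulates the data a genome-wide retrotransposon survey starts
from: an assembly carrying full-length LTR-RT copies of several subfamilies
(each copy = TSD + 5'LTR + internal region + 3'LTR + TSD, the internal region
carrying GAG/RT/integrase coding blocks in frame), whole-genome paired-end
resequencing reads, and a second genome that shares a controlled subset of
the insertion sites. Every planted copy is recorded in a :class:`SimTruth`
so recovery by the downstream stages can be scored exactly.

Ages are specified in million years; the planted LTR-LTR divergence follows
the molecular clock k = 2 r T with r the per-site per-year substitution rate,
so the dating stage applied to planted copies is an estimator of the planted
age. Substitutions are applied independently to the two LTR copies (k/2
each) under a Kimura-type process with a configurable transition:transversion
ratio; there are no indels in the mutation or sequencing-error models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    TRANSITION,
    TRANSVERSIONS,
    decode,
    derive_seed,
    encode,
    random_seq,
    revcomp,
)
from .profiles import GAG, INT, RT_COPIA, RT_GYPSY, _CONSENSUS, _flatten

DEFAULT_CLOCK_RATE = 4.72e-9  # substitutions / site / year

# one fixed codon per amino acid, used to embed domain peptides in frame
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


class SizingError(ValueError):
    """Planted material does not fit in the requested genome length."""


class SaturationError(ValueError):
    """Requested divergence is beyond the distance model's valid range."""


def encode_peptide(peptide: str) -> str:
    """Reverse-translate a peptide with the fixed codon table."""
    return "".join(_CODON[a] for a in peptide)


@dataclass(frozen=True)
class SubfamilySpec:
    """One planted LTR-RT subfamily."""

    name: str
    superfamily: str  # "copia" or "gypsy"
    ltr_length: int = 400
    internal_length: int = 4000
    copy_number: int = 5
    age_my: float | tuple[float, ...] = 1.0
    truncated_fraction: float = 0.0
    tsd_length: int = 5

    def __post_init__(self):
        if self.superfamily not in ("copia", "gypsy"):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if self.ltr_length < 50:
            raise ValueError("ltr_length below detector minimum")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        ages = self.ages()
        if any(a < 0 for a in ages):
            raise ValueError("age_my must be >= 0")

    def ages(self) -> list[float]:
        """Per-copy ages in MY (scalar spec broadcast to all copies)."""
        if isinstance(self.age_my, (int, float)):
            return [float(self.age_my)] * self.copy_number
        ages = [float(a) for a in self.age_my]
        if len(ages) != self.copy_number:
            raise ValueError("per-copy age list length != copy_number")
        return ages


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 500_000
    gc_content: float = 0.4
    subfamilies: tuple[SubfamilySpec, ...] = ()
    read_length: int = 100
    insert_size_mean: float = 350.0
    insert_size_sd: float = 30.0
    depth: float = 10.0
    error_rate: float = 0.001
    clock_rate: float = DEFAULT_CLOCK_RATE
    ts_tv_ratio: float = 2.0
    min_gap: int = 600  # minimum host bases between planted copies
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one planted copy (coordinates 0-based, half-open)."""

    copy_id: str
    subfamily: str
    superfamily: str
    contig: str
    start: int
    end: int
    strand: str
    ltr_length: int
    tsd: str
    divergence: float  # planted expected k between the two LTRs
    age_my: float
    truncated: bool
    shared_with_b: bool = False


@dataclass
class _Insertion:
    """Internal assembly-plan entry: one element at a background offset."""

    copy_id: str
    subfamily: str
    superfamily: str
    bg_pos: int  # insertion point in background coordinates
    element: str  # planted element sequence (strand applied)
    tsd_length: int
    strand: str
    ltr_length: int
    divergence: float
    age_my: float
    truncated: bool


@dataclass
class SimTruth:
    """Planted ground truth plus the assembly plan needed to rebuild/derive."""

    records: list[TruthRecord]
    templates: dict[str, tuple[str, str]]  # subfamily -> (ltr, internal)
    background: str = field(repr=False, default="")
    insertions: list[_Insertion] = field(repr=False, default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> list[dict]:
        return [vars(r).copy() for r in self.records]


def _apply_substitutions(
    codes: np.ndarray, rate: float, rng: np.random.Generator, ts_prob: float
) -> np.ndarray:
    """Kimura-process substitutions at expected ``rate`` events per site.

    Multiple hits per site are simulated (Poisson), so the *realised* identity
    saturates exactly as the distance models assume.
    """
    out = codes.copy()
    hits = rng.poisson(rate, size=len(codes))
    for pos in np.nonzero(hits)[0]:
        for _ in range(int(hits[pos])):
            if rng.random() < ts_prob:
                out[pos] = TRANSITION[out[pos]]
            else:
                out[pos] = TRANSVERSIONS[out[pos], rng.integers(2)]
    return out


def saturation_bound(model: str) -> float:
    """Largest representable divergence for each distance model."""
    return {"p-distance": 0.7, "JC69": 0.7, "K2P": 0.7}[model]


def mutate_ltr_pair(
    ltr: str,
    target_divergence: float,
    model: str = "K2P",
    seed: int = 0,
    ts_tv_ratio: float = 2.0,
) -> tuple[str, str]:
    """Mutate one LTR into a diverged 5'/3' pair.

    Substitutions are applied independently to each copy at an expected
    ``target_divergence / 2`` events per site so the expected model distance
    between the two outputs equals ``target_divergence``.
    """
    if target_divergence < 0:
        raise ValueError("target_divergence must be >= 0")
    if target_divergence >= saturation_bound(model):
        raise SaturationError(
            f"divergence {target_divergence} beyond {model} saturation"
        )
    rng = np.random.default_rng(seed)
    ts_prob = ts_tv_ratio / (ts_tv_ratio + 1.0)
    codes = encode(ltr)
    ltr5 = _apply_substitutions(codes, target_divergence / 2, rng, ts_prob)
    ltr3 = _apply_substitutions(codes, target_divergence / 2, rng, ts_prob)
    return decode(ltr5), decode(ltr3)


def _make_ltr_template(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random LTR with the canonical TG...CA termini."""
    return "TG" + random_seq(rng, length - 4, gc) + "CA"


SUBFAMILY_BLOCK_DIVERGENCE = 0.25  # nt divergence of each subfamily's
# domain coding blocks from the shared consensus, so subfamilies are related
# but well separated (real subfamilies differ throughout their coding region)


def _make_internal_template(
    rng: np.random.Generator, length: int, gc: float, superfamily: str,
    block_divergence: float = SUBFAMILY_BLOCK_DIVERGENCE,
) -> str:
    """Random internal region with GAG, RT and INT coding blocks in frame.

    Each coding block is a subfamily-private variant of the shared domain
    consensus, mutated at ``block_divergence`` substitutions per site.
    """
    rt = RT_COPIA if superfamily == "copia" else RT_GYPSY
    blocks = [
        decode(
            _apply_substitutions(
                encode(encode_peptide(_flatten(_CONSENSUS[d]))),
                block_divergence, rng, 2.0 / 3.0,
            )
        )
        for d in (GAG, rt, INT)
    ]
    coding = sum(map(len, blocks))
    spare = length - coding
    if spare < 8:
        raise ValueError(
            f"internal_length {length} cannot hold {coding} nt of domains"
        )
    # split the spare background into 4 deterministic pads
    pads = [spare // 4] * 3
    pads.append(spare - sum(pads))
    parts = []
    for pad, block in zip(pads, blocks + [""]):
        parts.append(random_seq(rng, pad, gc))
        parts.append(block)
    return "".join(parts)


def subfamily_templates(config: SimConfig) -> dict[str, tuple[str, str]]:
    """Deterministic (LTR, internal) template per subfamily."""
    out = {}
    for i, sub in enumerate(config.subfamilies):
        rng = np.random.default_rng(derive_seed(config.seed, 1, i))
        ltr = _make_ltr_template(rng, sub.ltr_length, config.gc_content)
        internal = _make_internal_template(
            rng, sub.internal_length, config.gc_content, sub.superfamily
        )
        out[sub.name] = (ltr, internal)
    return out


def _build_copy(
    sub: SubfamilySpec,
    templates: dict[str, tuple[str, str]],
    age_my: float,
    truncated: bool,
    clock_rate: float,
    ts_tv: float,
    gc: float,
    seed: int,
) -> tuple[str, float]:
    """One planted element sequence (without TSDs) and its true divergence."""
    ltr_t, internal_t = templates[sub.name]
    k = 2.0 * clock_rate * age_my * 1e6
    ltr5, ltr3 = mutate_ltr_pair(ltr_t, k, seed=seed, ts_tv_ratio=ts_tv)
    rng = np.random.default_rng(derive_seed(seed, 7))
    if truncated:
        internal = random_seq(rng, len(internal_t), gc)
    else:
        ts_prob = ts_tv / (ts_tv + 1.0)
        internal = decode(
            _apply_substitutions(encode(internal_t), k / 2, rng, ts_prob)
        )
    return ltr5 + internal + ltr3, k


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Build the synthetic genome and its ground truth.

    The returned genome is a single-contig dict {"chr1": sequence} whose total
    length equals ``config.genome_length`` exactly: planted material displaces
    background rather than extending the contig.
    """
    templates = subfamily_templates(config)
    rng = np.random.default_rng(derive_seed(config.seed, 0))

    # plan copies
    planned: list[tuple[SubfamilySpec, float, bool]] = []
    for sub in config.subfamilies:
        ages = sub.ages()
        n_trunc = int(round(sub.truncated_fraction * sub.copy_number))
        for j, age in enumerate(ages):
            planned.append((sub, age, j < n_trunc))

    total_planted = sum(
        len(templates[sub.name][0]) * 2 + len(templates[sub.name][1])
        + sub.tsd_length
        for sub, _, _ in planned
    )
    bg_len = config.genome_length - total_planted
    min_bg = (len(planned) + 1) * config.min_gap
    if bg_len < min_bg:
        raise SizingError(
            f"planted material ({total_planted} nt + {min_bg} nt spacing) "
            f"exceeds genome_length {config.genome_length}"
        )

    background = random_seq(rng, bg_len, config.gc_content)

    # non-adjacent insertion points in background coordinates
    n = len(planned)
    order = rng.permutation(n)  # shuffle copy order along the genome
    avail = bg_len - (n + 1) * config.min_gap
    u = np.sort(rng.random(n))
    positions = [
        int(u[i] * avail) + (i + 1) * config.min_gap for i in range(n)
    ]

    insertions: list[_Insertion] = []
    for rank, idx in enumerate(order):
        sub, age, truncated = planned[idx]
        copy_seed = derive_seed(config.seed, 2, int(idx))
        element, k = _build_copy(
            sub, templates, age, truncated, config.clock_rate,
            config.ts_tv_ratio, config.gc_content, copy_seed,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            element = revcomp(element)
        insertions.append(
            _Insertion(
                copy_id=f"{sub.name}.c{idx}",
                subfamily=sub.name,
                superfamily=sub.superfamily,
                bg_pos=positions[rank],
                element=element,
                tsd_length=sub.tsd_length,
                strand=strand,
                ltr_length=len(templates[sub.name][0]),
                divergence=k,
                age_my=age,
                truncated=truncated,
            )
        )

    genome_seq, records = _assemble(background, insertions, "chr1")
    truth = SimTruth(
        records=records,
        templates=templates,
        background=background,
        insertions=insertions,
    )
    return {"chr1": genome_seq}, truth


def _assemble(
    background: str, insertions: list[_Insertion], contig: str
) -> tuple[str, list[TruthRecord]]:
    """Splice insertions into the background, duplicating the TSD."""
    parts: list[str] = []
    records: list[TruthRecord] = []
    cursor = 0
    out_len = 0
    for ins in insertions:
        # TSD is the host sequence immediately after the insertion point
        sub_tsd_len = ins.tsd_length
        tsd = background[ins.bg_pos : ins.bg_pos + sub_tsd_len]
        chunk = background[cursor : ins.bg_pos + sub_tsd_len]
        parts.append(chunk)
        out_len += len(chunk)
        start = out_len
        parts.append(ins.element)
        out_len += len(ins.element)
        end = out_len
        parts.append(tsd)
        out_len += sub_tsd_len
        cursor = ins.bg_pos + sub_tsd_len
        records.append(
            TruthRecord(
                copy_id=ins.copy_id,
                subfamily=ins.subfamily,
                superfamily=ins.superfamily,
                contig=contig,
                start=start,
                end=end,
                strand=ins.strand,
                ltr_length=ins.ltr_length,
                tsd=tsd,
                divergence=ins.divergence,
                age_my=ins.age_my,
                truncated=ins.truncated,
            )
        )
    parts.append(background[cursor:])
    return "".join(parts), records


def simulate_reads(
    genome: dict[str, str], config: SimConfig
) -> list[tuple[str, str, str]]:
    """Uniform paired-end reads: (pair_id, read1, read2) triples.

    The pair count is deterministic:
    ``floor(depth * genome_length / (2 * read_length))``. Mate 2 is the
    reverse complement of the fragment end; substitution errors are applied
    per base at ``error_rate``. No indels, no quality modelling.
    """
    rng = np.random.default_rng(derive_seed(config.seed, 3))
    contigs = sorted(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    total = int(lengths.sum())
    rl = config.read_length
    if any(rl > len(genome[c]) for c in contigs):
        raise ValueError("read_length exceeds a contig length")
    n_pairs = int(config.depth * total / (2 * rl))
    codes = {c: encode(genome[c]) for c in contigs}

    which = rng.choice(len(contigs), size=n_pairs, p=lengths / lengths.sum())
    out: list[tuple[str, str, str]] = []
    for i in range(n_pairs):
        c = contigs[int(which[i])]
        clen = len(genome[c])
        frag = int(round(rng.normal(config.insert_size_mean,
                                    config.insert_size_sd)))
        frag = max(rl, min(frag, clen))
        start = int(rng.integers(0, clen - frag + 1))
        r1 = codes[c][start : start + rl].copy()
        r2 = (3 - codes[c][start + frag - rl : start + frag])[::-1].copy()
        for r in (r1, r2):
            if config.error_rate > 0:
                errs = np.nonzero(rng.random(rl) < config.error_rate)[0]
                for pos in errs:
                    r[pos] = (r[pos] + rng.integers(1, 4)) % 4
        out.append((f"pair{i}", decode(r1), decode(r2)))
    return out


def derive_second_genome(
    genome: dict[str, str],
    truth: SimTruth,
    shared_fraction: float,
    seed: int = 0,
    extra_specific: int = 0,
    extra_age_my: float = 0.5,
) -> tuple[dict[str, str], SimTruth]:
    """Second genome keeping each planted insertion with prob shared_fraction.

    Dropped insertions are removed seamlessly (the single host TSD remains,
    because the background is untouched). ``extra_specific`` additional
    genome-B-only copies are planted, drawn round-robin from the existing
    subfamily templates, at fresh background positions. The input ``truth``
    is not modified; use :func:`apply_sharing_flags` to stamp the A-side
    records with their realised sharing status.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(truth.insertions)) < shared_fraction
    kept: list[_Insertion] = [
        ins for ins, k in zip(truth.insertions, keep) if k
    ]

    superfam = {i.subfamily: i.superfamily for i in truth.insertions}
    extras: list[_Insertion] = []
    if extra_specific:
        subnames = sorted(truth.templates)
        occupied = sorted(i.bg_pos for i in truth.insertions)
        bg_len = len(truth.background)
        for j in range(extra_specific):
            name = subnames[j % len(subnames)]
            ltr_t, internal_t = truth.templates[name]
            k_div = 2.0 * DEFAULT_CLOCK_RATE * extra_age_my * 1e6
            cseed = derive_seed(seed, 11, j)
            ltr5, ltr3 = mutate_ltr_pair(ltr_t, k_div, seed=cseed)
            pos = _free_position(rng, bg_len, occupied, 600)
            occupied.append(pos)
            occupied.sort()
            extras.append(
                _Insertion(
                    copy_id=f"{name}.b{j}",
                    subfamily=name,
                    superfamily=superfam.get(name, "copia"),
                    bg_pos=pos,
                    element=ltr5 + internal_t + ltr3,
                    tsd_length=5,
                    strand="+",
                    ltr_length=len(ltr_t),
                    divergence=k_div,
                    age_my=extra_age_my,
                    truncated=False,
                )
            )

    all_ins = sorted(kept + extras, key=lambda i: i.bg_pos)
    contig = next(iter(genome))
    genome_b_seq, records_b = _assemble(truth.background, all_ins, contig)
    shared_ids = {i.copy_id for i in kept}
    for r in records_b:
        r.shared_with_b = r.copy_id in shared_ids
    truth_b = SimTruth(
        records=records_b,
        templates=truth.templates,
        background=truth.background,
        insertions=all_ins,
    )
    return {contig: genome_b_seq}, truth_b


def apply_sharing_flags(truth: SimTruth, truth_b: SimTruth) -> None:
    """Stamp genome-A truth records with the sharing realised in genome B."""
    shared = {r.copy_id for r in truth_b.records if r.shared_with_b}
    for r in truth.records:
        r.shared_with_b = r.copy_id in shared


def _free_position(
    rng: np.random.Generator, bg_len: int, occupied: list[int], gap: int
) -> int:
    for _ in range(10_000):
        pos = int(rng.integers(gap, bg_len - gap))
        if all(abs(pos - o) >= gap for o in occupied):
            return pos
    raise SizingError("no free background position for extra insertion")


def expected_divergence(age_my: float, clock_rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Molecular-clock divergence implied by an age: k = 2 r T."""
    return 2.0 * clock_rate * age_my * 1e6
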