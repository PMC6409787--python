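"""Lineage assignment of reverse-transcriptase peptides by neighbor joining.

Each LTR-RT superfamily is subdivided into named deep lineages (for copia:
Ivana, Ale, Maximus, TAR, Bianca, Angela; for gypsy: Tekay, CRM, Athila, Tat,
Galadriel, Reina), conventionally assigned by clustering the element's
reverse-transcriptase peptide with reference exemplars of each lineage in a
neighbor-joining tree. The two superfamilies are always clustered in
separate trees.

The packaged lineage exemplar peptides are synthetic stand-ins derived from
the superfamily RT consensus by fixed per-lineage divergence (they make the
procedure runnable and testable without database access); users with curated
exemplars can pass their own.
"""
from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from ._seq import derive_seed
from .align import prot_identity_distance
from .profiles import RT_COPIA, RT_GYPSY, best_six_frame_window, default_profiles

COPIA_LINEAGES = ("Ivana", "Ale", "Maximus", "TAR", "Bianca", "Angela")
GYPSY_LINEAGES = ("Tekay", "CRM", "Athila", "Tat", "Galadriel", "Reina")

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RtPeptide:
    id: str
    superfamily: str     # "copia" | "gypsy"
    sequence: str
    source: str          # "query" | "reference"
    lineage: str | None = None   # references only

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty RT peptide")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def triangle_violations(self) -> int:
        """Count of (i,j,k) with d(i,j) > d(i,k) + d(k,j); NJ tolerates
        these but callers may want to know."""
        v, n = self.values, len(self.labels)
        viol = 0
        for i in range(n):
            for j in range(i + 1, n):
                if (v[i, j] > v[i] + v[j] + 1e-12).any():
                    viol += 1
        return viol


def extract_rt_peptide(element, profiles=None) -> RtPeptide:
    """Best six-frame RT window of an element's internal region."""
    profiles = profiles or default_profiles()
    rt_name = RT_COPIA if element.superfamily == "copia" else RT_GYPSY
    if rt_name not in element.domains_found:
        raise ValueError(
            f"element {element.id} has no {rt_name} hit; run the domain "
            "filter first and keep only RT-bearing elements"
        )
    pep = best_six_frame_window(profiles[rt_name], element.sequence)
    if pep is None:
        raise ValueError(f"element {element.id}: no RT window found")
    return RtPeptide(element.id, element.superfamily, pep, "query")


def protein_distance_matrix(peptides: list[RtPeptide]) -> DistanceMatrix:
    """Pairwise 1 - identity distances from global protein alignments."""
    if len(peptides) < 3:
        raise ValueError("need at least 3 peptides")
    labels = [p.id for p in peptides]
    n = len(peptides)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = prot_identity_distance(
                peptides[i].sequence, peptides[j].sequence
            )
    return DistanceMatrix(labels, d)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining with deterministic tie-breaking.

    Q-criterion joins; branch lengths by the standard formulas, negative
    lengths clamped to zero. Ties in Q are broken by label order. Returns an
    unrooted tree represented as a trifurcating-root scikit-bio TreeNode.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = matrix.values.astype(float).copy()
    nodes = [TreeNode(name=lbl) for lbl in labels]
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = (q, nodes[active[ai]].name or "",
                       nodes[active[aj]].name or "")
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += 1
            lj, li = dij, 0.0
        if lj < 0:
            clamped += 1
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for other in active:
            if other in (i, j):
                continue
            new_row[other] = 0.5 * (d[i, other] + d[j, other] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # resolve the last three nodes around an unrooted central vertex
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        if ln < 0:
            clamped += 1
            ln = 0.0
        nodes[idx].length = float(ln)
        root.append(nodes[idx])
    if clamped:
        root.comment = f"{clamped} negative branch length(s) clamped to 0"
    return root


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def assign_lineage(
    tree: TreeNode,
    query_ids: list[str],
    reference_lineages: dict[str, str],
) -> dict[str, tuple[str, bool]]:
    """Assign each query the lineage of its smallest enclosing reference clade.

    Walking rootward from the query tip, the first ancestor whose subtree
    contains at least one reference decides: if all its references belong to
    one lineage the query takes that lineage unambiguously; otherwise the
    query takes the lineage of the nearest reference by path length and is
    flagged ambiguous. Returns {query_id: (lineage, ambiguous)}.
    """
    if not reference_lineages:
        raise ValueError("no reference exemplars in tree")
    tips = {t.name: t for t in tree.tips()}
    out: dict[str, tuple[str, bool]] = {}
    for qid in query_ids:
        tip = tips[qid]
        node = tip.parent
        decided = None
        while node is not None:
            refs = [t.name for t in node.tips()
                    if t.name in reference_lineages and t.name != qid]
            if refs:
                lineages = {reference_lineages[r] for r in refs}
                if len(lineages) == 1:
                    decided = (lineages.pop(), False)
                else:
                    nearest = min(
                        refs,
                        key=lambda r: (tip.distance(tips[r]), r),
                    )
                    decided = (reference_lineages[nearest], True)
                break
            node = node.parent
        if decided is None:
            raise ValueError("tree has no reference exemplars")
        out[qid] = decided
    return out


def reference_rt_peptides(superfamily: str, divergence: float = 0.35,
                          seed: int = 20) -> list[RtPeptide]:
    """Synthetic lineage exemplar peptides for one superfamily.

    Each exemplar is the superfamily RT consensus with a fixed fraction of
    residues (``divergence``) replaced at lineage-specific positions, so
    exemplars are equidistant from the consensus but mutually distinct.
    """
    profiles = default_profiles()
    if superfamily == "copia":
        base = profiles[RT_COPIA].consensus
        lineages = COPIA_LINEAGES
    elif superfamily == "gypsy":
        base = profiles[RT_GYPSY].consensus
        lineages = GYPSY_LINEAGES
    else:
        raise ValueError(f"unknown superfamily {superfamily!r}")
    out = []
    for li, lineage in enumerate(lineages):
        rng = np.random.default_rng(derive_seed(seed, li))
        pep = list(base)
        n_mut = int(round(divergence * len(pep)))
        for pos in rng.choice(len(pep), size=n_mut, replace=False):
            choices = [a for a in _AA if a != pep[pos]]
            pep[pos] = choices[int(rng.integers(len(choices)))]
        out.append(
            RtPeptide(f"{lineage}_ref", superfamily, "".join(pep),
                      "reference", lineage)
        )
    return out


def mutate_peptide(peptide: str, divergence: float, seed: int) -> str:
    """Point-mutate a peptide at ``divergence`` fraction of residues."""
    rng = np.random.default_rng(seed)
    pep = list(peptide)
    n_mut = int(round(divergence * len(pep)))
    for pos in rng.choice(len(pep), size=n_mut, replace=False):
        choices = [a for a in _AA if a != pep[pos]]
        pep[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(pep)


def cluster_lineages(
    queries: list[RtPeptide],
    references: list[RtPeptide] | None = None,
) -> dict[str, tuple[str, bool]]:
    """End-to-end lineage assignment, one NJ tree per superfamily."""
    out: dict[str, tuple[str, bool]] = {}
    for superfamily in ("copia", "gypsy"):
        qs = [q for q in queries if q.superfamily == superfamily]
        if not qs:
            continue
        refs = [r for r in (references or []) if r.superfamily == superfamily]
        if not refs:
            refs = reference_rt_peptides(superfamily)
        matrix = protein_distance_matrix(qs + refs)
        tree = nj_tree(matrix)
        ref_lineages = {r.id: r.lineage for r in refs}
        out.update(assign_lineage(tree, [q.id for q in qs], ref_lineages))
    return out
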