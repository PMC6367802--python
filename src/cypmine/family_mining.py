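"""Identification and phylogeny of P450-like protein families.

Cytochrome P450 proteins carry four diagnostic motifs — the heme-binding
domain with its invariant cysteine, the I-helix, the K-helix ExxR core and
the PERF/W domain.  A protein is called a family member when all four motifs
are present and its length falls in a configured window (default 450-600 aa,
the range of full-length plant P450s).

Downstream of mining, this module computes percent-identity matrices,
per-column conservation (sequence-logo information content), p-distance /
Poisson-corrected distances, Saitou-Nei neighbor-joining trees with bootstrap
support, and identity-threshold family/subfamily groupings following the P450
nomenclature convention (40% family, 55% subfamily).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import AMINO_ACIDS, ProteinRecord, Tree, TreeNode

# ---------------------------------------------------------------------------
# Signature profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureProfile:
    """A degenerate protein pattern: fixed residues, [XY] alternatives, wildcard x."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.positions()) < 4:
            raise ValueError(f"profile {self.name!r}: pattern too short")

    def positions(self) -> list[frozenset[str]]:
        """Expand the pattern into a per-position set of allowed residues."""
        out: list[frozenset[str]] = []
        i, pat = 0, self.pattern
        while i < len(pat):
            c = pat[i]
            if c == "[":
                j = pat.index("]", i)
                out.append(frozenset(pat[i + 1:j]))
                i = j + 1
            elif c == "x":
                out.append(frozenset(AMINO_ACIDS))
                i += 1
            else:
                out.append(frozenset(c))
                i += 1
        return out


#: Minimal patterns consistent with the conserved-motif logos of plant P450s.
#: The heme motif keeps the invariant cysteine; the I-helix first position
#: admits A or G; PERF/W allows the F/W alternative.  All are user-overridable.
DEFAULT_PROFILES: tuple[SignatureProfile, ...] = (
    SignatureProfile("heme", "FxxGxRxCxG"),
    SignatureProfile("i_helix", "[AG]GxDT"),
    SignatureProfile("k_helix", "ExxR"),
    SignatureProfile("perf", "PER[FW]"),
)

DEFAULT_LENGTH_BOUNDS: tuple[int, int] = (450, 600)


def scan_signatures(protein: ProteinRecord,
                    profiles: tuple[SignatureProfile, ...] = DEFAULT_PROFILES,
                    ) -> dict[str, list[int]]:
    """Find every match start (0-based) of each signature in an ungapped protein."""
    if "-" in protein.sequence:
        raise ValueError(f"protein {protein.protein_id!r} is gapped; ungap first")
    seq = protein.sequence
    hits: dict[str, list[int]] = {}
    for prof in profiles:
        pos = prof.positions()
        m = len(pos)
        found = [i for i in range(len(seq) - m + 1)
                 if all(seq[i + j] in pos[j] for j in range(m))]
        hits[prof.name] = found
    return hits


@dataclass
class CandidateCall:
    """Outcome of the signature + length filter for one protein."""

    protein_id: str
    length: int
    motif_hits: dict[str, list[int]]
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)


def filter_candidates(proteins: list[ProteinRecord],
                      profiles: tuple[SignatureProfile, ...] = DEFAULT_PROFILES,
                      length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
                      ) -> list[CandidateCall]:
    """Call family members: all signature motifs present and length in bounds.

    Exact-duplicate sequences are collapsed to the first-seen record
    (redundancy removal); the IDs of the collapsed duplicates are listed on
    the surviving call.
    """
    lo, hi = length_bounds
    if lo > hi:
        raise ValueError("length_bounds min > max")
    calls: list[CandidateCall] = []
    first_by_seq: dict[str, CandidateCall] = {}
    for p in proteins:
        seq = p.ungapped()
        if seq in first_by_seq:
            first_by_seq[seq].duplicates.append(p.protein_id)
            continue
        hits = scan_signatures(ProteinRecord(p.protein_id, seq), profiles)
        reasons = [f"missing_{name}" for name, hh in hits.items() if not hh]
        if not lo <= len(seq) <= hi:
            reasons.append("length")
        call = CandidateCall(
            protein_id=p.protein_id, length=len(seq), motif_hits=hits,
            passed=not reasons, fail_reasons=reasons,
        )
        calls.append(call)
        first_by_seq[seq] = call
    return calls


# ---------------------------------------------------------------------------
# Alignment statistics
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """A gapped multiple protein alignment with equal-length rows."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned records have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    def labels(self) -> list[str]:
        return [r.protein_id for r in self.records]

    def subsample_columns(self, columns: np.ndarray) -> "AlignmentBlock":
        return AlignmentBlock([
            ProteinRecord(r.protein_id, "".join(r.sequence[c] for c in columns))
            for r in self.records
        ])


@dataclass
class DistanceMatrix:
    """A symmetric labelled distance (or percent-identity) matrix.

    `undefined` holds label pairs where the measure could not be computed
    (no comparable columns, or a saturated Poisson correction).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(np.nan_to_num(v)), 0.0):
            raise ValueError("diagonal not zero")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _pairwise_counts(seq_i: str, seq_j: str) -> tuple[int, int]:
    """(matches, comparable columns) over positions where neither row is a gap."""
    comparable = matches = 0
    for a, b in zip(seq_i, seq_j):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            matches += 1
    return matches, comparable


def identity_matrix(alignment: AlignmentBlock) -> DistanceMatrix:
    """Pairwise percent identity: 100 x matches / gap-free comparable columns."""
    labels = alignment.labels()
    n = len(labels)
    vals = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            m, c = _pairwise_counts(alignment.records[i].sequence,
                                    alignment.records[j].sequence)
            if c == 0:
                vals[i, j] = vals[j, i] = np.nan
                undefined.add((labels[i], labels[j]))
            else:
                vals[i, j] = vals[j, i] = 100.0 * m / c
    return DistanceMatrix(labels, vals, kind="percent_identity",
                          undefined=undefined)


def column_conservation(alignment: AlignmentBlock,
                        ) -> list[tuple[dict[str, float], float | None]]:
    """Per-column residue frequencies and information content in bits.

    Information = log2(20) - Shannon entropy of the gap-excluded residue
    distribution (the quantity a sequence logo draws).  All-gap columns have
    undefined information, returned as None.
    """
    max_bits = math.log2(len(AMINO_ACIDS))
    out: list[tuple[dict[str, float], float | None]] = []
    for c in range(alignment.n_columns):
        col = [r.sequence[c] for r in alignment.records if r.sequence[c] != "-"]
        if not col:
            out.append(({}, None))
            continue
        freqs: dict[str, float] = {}
        for aa in col:
            freqs[aa] = freqs.get(aa, 0.0) + 1.0
        total = len(col)
        freqs = {aa: k / total for aa, k in sorted(freqs.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        out.append((freqs, max_bits - entropy))
    return out


def protein_distances(alignment: AlignmentBlock,
                      model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances: p-distance or its Poisson correction -ln(1-p).

    A Poisson distance is undefined (infinite) when p >= 1; the pair is
    flagged in `undefined` and the cell set to +inf.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    labels = alignment.labels()
    n = len(labels)
    vals = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            m, c = _pairwise_counts(alignment.records[i].sequence,
                                    alignment.records[j].sequence)
            if c == 0:
                vals[i, j] = vals[j, i] = np.nan
                undefined.add((labels[i], labels[j]))
                continue
            p = 1.0 - m / c
            if model == "p_distance":
                d = p
            elif p >= 1.0:
                d = np.inf
                undefined.add((labels[i], labels[j]))
            else:
                d = -math.log(1.0 - p)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, kind=model, undefined=undefined)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising the Q-criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j, with branch lengths from the
    rate-corrected formulas.  Ties are broken by lexicographic label order
    (each internal node is keyed by its smallest descendant leaf label).
    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch.  Returns an unrooted tree with a trifurcating root.
    """
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d.values)):
        raise ValueError("distance matrix contains non-finite entries")

    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]
    keys: list[str] = list(d.labels)  # tie-break key: smallest leaf below
    dist: list[list[float]] = [list(row) for row in d.values]

    def join_once() -> None:
        n = len(nodes)
        r = [sum(dist[i]) for i in range(n)]
        best = None
        # pair minimising Q; ties broken by sorted tie-break keys
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dist[i][j] - r[i] - r[j]
                a, b = sorted((keys[i], keys[j]))
                cand = (q, a, b, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        dij = dist[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, njn = nodes[i], nodes[j]
        ni.length, njn.length = li, lj
        new = TreeNode(children=[ni, njn])
        new_key = min(keys[i], keys[j])
        new_row = [0.5 * (dist[i][k] + dist[j][k] - dij)
                   for k in range(n) if k not in (i, j)]
        for idx in sorted((i, j), reverse=True):
            del nodes[idx], keys[idx], dist[idx]
            for row in dist:
                del row[idx]
        for row, val in zip(dist, new_row):
            row.append(val)
        dist.append(new_row + [0.0])
        nodes.append(new)
        keys.append(new_key)

    while len(nodes) > 3:
        join_once()

    # resolve the final three nodes with the three-point formulas
    a, b, c = nodes
    dab, dac, dbc = dist[0][1], dist[0][2], dist[1][2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return Tree(root=TreeNode(children=[a, b, c]))


def bootstrap_support(alignment: AlignmentBlock, B: int = 1000,
                      seed: int = 0, model: str = "p_distance") -> Tree:
    """NJ tree of the alignment with bootstrap support on internal branches.

    Columns are resampled with replacement B times; the support of each
    internal branch of the original tree is the percentage of replicate NJ
    trees containing the same leaf bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = nj_tree(protein_distances(alignment, model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep = alignment.subsample_columns(cols)
        rep_tree = nj_tree(protein_distances(rep, model))
        for bp in rep_tree.bipartitions() & target:
            counts[bp] += 1

    all_leaves = frozenset(tree.leaf_labels())

    def annotate(n: TreeNode) -> frozenset[str]:
        if n.is_leaf():
            return frozenset([n.label])
        below = frozenset().union(*(annotate(c) for c in n.children))
        if n is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            bp = min(below, other, key=lambda s: (len(s), sorted(s)))
            n.support = 100.0 * counts[bp] / B
        return below

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Family / subfamily assignment
# ---------------------------------------------------------------------------

def _single_linkage(labels: list[str], identity: np.ndarray,
                    cut: float) -> list[list[str]]:
    """Connected components of the identity >= cut graph (single linkage)."""
    n = len(labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] >= cut:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(labels[i])
    clusters = [sorted(m) for m in comps.values()]
    clusters.sort(key=lambda m: (-len(m), m))
    return clusters


def assign_groups(d: DistanceMatrix, family_cut: float = 40.0,
                  subfamily_cut: float = 55.0) -> dict[str, tuple[str, str]]:
    """Family and subfamily labels by identity-threshold single linkage.

    Families are single-linkage clusters at >= family_cut percent identity
    (P450 convention 40%), subfamilies at >= subfamily_cut (55%) nested within
    each family.  Clusters are numbered by decreasing size, then by the
    lexicographically smallest member.
    """
    if d.kind != "percent_identity":
        raise ValueError("assign_groups expects a percent-identity matrix")
    values = np.nan_to_num(d.values, nan=0.0)
    families = _single_linkage(d.labels, values, family_cut)
    out: dict[str, tuple[str, str]] = {}
    for fi, fam in enumerate(families, 1):
        idx = [d.labels.index(m) for m in fam]
        sub_vals = values[np.ix_(idx, idx)]
        subs = _single_linkage(fam, sub_vals, subfamily_cut)
        for si, sub in enumerate(subs, 1):
            for member in sub:
                out[member] = (f"F{fi}", f"F{fi}.S{si}")
    return out
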