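"""Intron maps: projection to protein coordinates, insertion sites, censuses.

An intron falling after k coding nucleotides sits in codon floor(k/3)+1
(1-based) with phase k mod 3 — phase 0 between codons, phase 1 after the
first nucleotide of a codon, phase 2 after the second.  Introns from many
genes are clustered (within a phase class) into insertion sites, each
interpreted as one ancestral gain event; a site is a conserved intron when
its members share the phase and all lie within a fixed amino-acid window of
the site's mean position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_core import GeneModel, percent

DEFAULT_WINDOW = 45.0  # aa; the conservation window (range 40-45 in practice)
DEFAULT_MIN_GENES = 2

CENSUS_CLASSES = ("0", "1", "2", "3", "4", "5+")


@dataclass(frozen=True)
class IntronRecord:
    """One intron in protein coordinates.

    k is the number of coding nucleotides 5' of the intron; the codon index
    and phase follow from it.
    """

    gene_id: str
    k: int
    aa_position: int  # floor(k/3) + 1, 1-based codon index
    phase: int  # k mod 3

    @classmethod
    def from_k(cls, gene_id: str, k: int) -> "IntronRecord":
        return cls(gene_id=gene_id, k=k, aa_position=k // 3 + 1, phase=k % 3)


@dataclass
class InsertionSite:
    """A cross-gene cluster of introns: one inferred insertion event."""

    site_id: str
    phase: int
    members: list[tuple[str, int]]  # (gene_id, aa_position)
    mean_position: float
    conserved: bool = False
    #: per-member phases; None when the site came from per-phase clustering,
    #: where all members share `phase` by construction
    member_phases: list[int] | None = None


@dataclass
class IntronCensus:
    """Counts and percentages of genes per intron-number class, plus phases."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]
    phase_counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: dict[str, int],
                    phase_counts: dict[int, int] | None = None) -> "IntronCensus":
        counts = {c: int(counts.get(c, 0)) for c in CENSUS_CLASSES}
        total = sum(counts.values())
        if total < 1:
            raise ValueError("census needs at least one gene")
        pct = {c: percent(k, total) for c, k in counts.items()}
        return cls(counts=counts, total=total, percentages=pct,
                   phase_counts=phase_counts or {})


def introns_from_genemodel(g: GeneModel) -> list[IntronRecord]:
    """Project a gene's introns onto protein coordinates, strand-aware.

    One record per junction between consecutive CDS segments; k is the
    cumulative CDS length 5' (in transcription direction) of the junction.
    Introns lying entirely in the UTR contribute no CDS junction and are
    therefore excluded.  Single-exon genes yield an empty list.
    """
    if g.cds_length() == 0:
        raise ValueError(f"gene {g.gene_id!r} has zero CDS length")
    segments = g.cds if g.strand == "+" else list(reversed(g.cds))
    records: list[IntronRecord] = []
    k = 0
    for s, e in segments[:-1]:
        k += e - s
        records.append(IntronRecord.from_k(g.gene_id, k))
    return records


def cluster_insertion_sites(introns: list[IntronRecord],
                            window: float = DEFAULT_WINDOW) -> list[InsertionSite]:
    """Group introns into insertion sites by phase, then position.

    Within each phase class, amino-acid positions are single-linkage
    clustered with link threshold = window (in 1D this splits sorted
    positions wherever the gap between neighbours exceeds the window).
    Sites are numbered I1..In by ascending mean position across all phases;
    every intron belongs to exactly one site.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    raw_sites: list[tuple[float, int, list[tuple[str, int]]]] = []
    for phase in (0, 1, 2):
        members = sorted(
            ((r.aa_position, r.gene_id) for r in introns if r.phase == phase))
        if not members:
            continue
        cluster: list[tuple[str, int]] = [(members[0][1], members[0][0])]
        last_pos = members[0][0]
        for pos, gid in members[1:]:
            if pos - last_pos > window:
                mean = sum(p for _, p in cluster) / len(cluster)
                raw_sites.append((mean, phase, cluster))
                cluster = []
            cluster.append((gid, pos))
            last_pos = pos
        mean = sum(p for _, p in cluster) / len(cluster)
        raw_sites.append((mean, phase, cluster))
    raw_sites.sort(key=lambda t: (t[0], t[1]))
    return [
        InsertionSite(site_id=f"I{i}", phase=phase, members=members,
                      mean_position=mean)
        for i, (mean, phase, members) in enumerate(raw_sites, 1)
    ]


def call_conserved(sites: list[InsertionSite], window: float = DEFAULT_WINDOW,
                   min_genes: int = DEFAULT_MIN_GENES,
                   require_same_phase: bool = True) -> list[InsertionSite]:
    """Flag conserved introns.

    A site is conserved when every member lies within `window` amino acids of
    the site's mean position, the members share one phase (guaranteed by the
    per-phase clustering unless disabled upstream), and at least `min_genes`
    distinct genes carry it.
    """
    for site in sites:
        genes = {g for g, _ in site.members}
        within = all(abs(p - site.mean_position) <= window
                     for _, p in site.members)
        phase_ok = (not require_same_phase
                    or site.member_phases is None  # uniform by construction
                    or len(set(site.member_phases)) == 1)
        site.conserved = within and phase_ok and len(genes) >= min_genes
    return sites


def intron_census(gene_models: list[GeneModel]) -> IntronCensus:
    """Census of intron numbers per gene over the classes 0,1,2,3,4,5+.

    Percentages are 100 x count / total, rounded half-up to two decimals;
    raw counts are carried so any rounding convention can be audited.
    Phase counts tally every intron of every gene.
    """
    if not gene_models:
        raise ValueError("census needs at least one gene")
    counts = {c: 0 for c in CENSUS_CLASSES}
    phase_counts = {0: 0, 1: 0, 2: 0}
    for g in gene_models:
        recs = introns_from_genemodel(g)
        n = len(recs)
        counts["5+" if n >= 5 else str(n)] += 1
        for r in recs:
            phase_counts[r.phase] += 1
    return IntronCensus.from_counts(counts, phase_counts)


def gain_loss_matrix(sites: list[InsertionSite],
                     group_labels: dict[str, str],
                     ) -> tuple[list[str], list[str], list[list[int]]]:
    """Family x site presence table: cell 1 iff any family gene hits the site.

    Returns (family row labels sorted, site column labels in site order,
    matrix of 0/1).  A site member whose gene has no family label is an error.
    """
    for site in sites:
        for gid, _ in site.members:
            if gid not in group_labels:
                raise ValueError(f"gene {gid!r} has no family label")
    families = sorted(set(group_labels.values()))
    site_ids = [s.site_id for s in sites]
    fam_idx = {f: i for i, f in enumerate(families)}
    matrix = [[0] * len(sites) for _ in families]
    for j, site in enumerate(sites):
        for gid, _ in site.members:
            matrix[fam_idx[group_labels[gid]]][j] = 1
    return families, site_ids, matrix


def intron_map_text(sites: list[InsertionSite],
                    gene_ids: list[str] | None = None,
                    scale: int = 10) -> str:
    """Text-art intron map: one row per gene, phase glyphs at aa/scale columns.

    Glyphs follow the conventional legend: '|' phase 0, '[' phase 1,
    ']' phase 2.  Site IDs are printed above their mean positions.
    """
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for site in sites:
        for gid, pos in site.members:
            by_gene.setdefault(gid, []).append((pos, site.phase))
    if gene_ids is None:
        gene_ids = sorted(by_gene)
    width = max((max(p for p, _ in v) for v in by_gene.values()), default=0)
    ncol = width // scale + 2
    glyph = {0: "|", 1: "[", 2: "]"}
    name_w = max((len(g) for g in gene_ids), default=4) + 2

    header = [" "] * ncol
    for site in sites:
        col = int(site.mean_position) // scale
        for i, ch in enumerate(site.site_id):
            if col + i < ncol:
                header[col + i] = ch
    lines = [" " * name_w + "".join(header)]
    for gid in gene_ids:
        row = ["-"] * ncol
        for pos, phase in by_gene.get(gid, []):
            row[pos // scale] = glyph[phase]
        lines.append(gid.ljust(name_w) + "".join(row))
    return "\n".join(lines)
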