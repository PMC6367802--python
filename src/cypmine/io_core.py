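"""Shared domain types, file I/O and conventions.

All internal coordinates are 0-based half-open; conversion to/from the 1-based
inclusive conventions of GFF3 happens only at the file boundary.  Sequences are
uppercased on read.  Every reader/writer pair here is a round-trip identity on
valid inputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("cypmine")

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def setup_logging(verbose: bool = False) -> None:
    """Configure stderr logging for the command-line entry points."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as used for all percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """count/total as a percentage, rounded half-up to `ndigits` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """One contig of genomic DNA (A/C/G/T/N, uppercase)."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-DNA letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """A protein sequence, optionally gapped when part of an alignment."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.ungapped():
            raise ValueError(f"protein {self.protein_id!r} has no residues")

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """One gene's structure on a contig: exons, CDS segments, strand and TSS.

    Only one mRNA per gene is represented.  Intervals are sorted by start and
    non-overlapping; the CDS is contained in the exon union and its total
    length is a multiple of 3.  The TSS is the leftmost genomic coordinate on
    the + strand and the rightmost covered base (end - 1) on the - strand.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"gene {self.gene_id!r}: overlapping {name}")
            for s, e in ivs:
                if not 0 <= s < e:
                    raise ValueError(f"gene {self.gene_id!r}: bad interval ({s},{e})")
        if self.cds and not self._cds_within_exons():
            raise ValueError(f"gene {self.gene_id!r}: CDS not contained in exons")
        if self.cds_length() % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: CDS length {self.cds_length()} "
                "not divisible by 3"
            )
        if self.tss is None:
            self.tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    def _cds_within_exons(self) -> bool:
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                return False
        return True

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def protein_length(self) -> int:
        return self.cds_length() // 3


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a phylogenetic tree; leaves carry labels, edges carry lengths."""

    label: str | None = None
    length: float = 0.0  # length of the edge above this node
    support: float | None = None  # bootstrap support of the edge above, 0-100
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (usually trifurcating) root."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical leaf set.

        Each internal edge splits the leaves in two; the split is represented
        by the frozenset of labels on the child side, canonicalised so that
        the same split from either side compares equal.
        """
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(n: TreeNode) -> frozenset[str]:
            if n.is_leaf():
                return frozenset([n.label])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return splits

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths keyed by sorted label pair."""
        dists: dict[tuple[str, str], float] = {}

        def walk(n: TreeNode) -> dict[str, float]:
            if n.is_leaf():
                return {n.label: 0.0}
            sub = [{a: da + c.length for a, da in walk(c).items()}
                   for c in n.children]
            for i, di in enumerate(sub):
                for dj in sub[i + 1:]:
                    for a, da in di.items():
                        for b, db in dj.items():
                            dists[tuple(sorted((a, b)))] = da + db
            merged: dict[str, float] = {}
            for d in sub:
                merged.update(d)
            return merged

        walk(self.root)
        return dists


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str, kind: str = "dna") -> list[GenomeSequence] | list[ProteinRecord]:
    """Read a FASTA file into GenomeSequence ('dna') or ProteinRecord ('protein').

    Order is preserved, sequences are uppercased.  An empty file or a
    duplicated record ID is an error.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"{path}: duplicate record ID {r.id!r}")
        seen.add(r.id)
    if kind == "dna":
        return [GenomeSequence(r.id, str(r.seq)) for r in records]
    if kind == "protein":
        return [ProteinRecord(r.id, str(r.seq)) for r in records]
    raise ValueError(f"unknown kind {kind!r}")


def write_fasta(records: Iterable[GenomeSequence | ProteinRecord], path: str,
                width: int = 70) -> None:
    seqs = []
    for r in records:
        rid = r.contig_id if isinstance(r, GenomeSequence) else r.protein_id
        seqs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels, one per gene (first mRNA only).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    A CDS whose total length is not a multiple of 3, or an mRNA/exon/CDS with
    no Parent link, is an error naming the offending feature.
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            raise ValueError(f"gene {gene.id!r}: no mRNA child with Parent link")
        if len(mrnas) > 1:
            log.warning("gene %s has %d mRNAs; using the first", gene.id, len(mrnas))
        mrna = mrnas[0]
        exons = [(f.start - 1, f.end)
                 for f in db.children(mrna, featuretype="exon", order_by="start")]
        cds = [(f.start - 1, f.end)
               for f in db.children(mrna, featuretype="CDS", order_by="start")]
        if not exons:
            exons = list(cds)
        total_cds = sum(e - s for s, e in cds)
        if total_cds % 3 != 0:
            raise ValueError(
                f"gene {gene.id!r}: CDS length {total_cds} not divisible by 3")
        models.append(GeneModel(
            gene_id=gene.id, contig_id=gene.seqid, strand=gene.strand,
            exons=exons, cds=cds,
        ))
    return models


def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    """Emit standard GFF3 (1-based inclusive) with gene/mRNA/exon/CDS rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            start = min(s for s, _ in g.exons) + 1
            end = max(e for _, e in g.exons)
            mrna_id = f"{g.gene_id}.1"
            fh.write(f"{g.contig_id}\tcypmine\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.contig_id}\tcypmine\tmRNA\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.contig_id}\tcypmine\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n")
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(f"{g.contig_id}\tcypmine\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n")


def write_bed6(rows: Iterable[tuple[str, int, int, str, int | float, str]],
               path: str) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand); 0-based half-open."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def tree_to_newick(tree: Tree, include_support: bool = True) -> str:
    def fmt(n: TreeNode, top: bool) -> str:
        if n.is_leaf():
            body = n.label
        else:
            body = "(" + ",".join(fmt(c, False) for c in n.children) + ")"
            if include_support and n.support is not None:
                body += f"{n.support:g}"
        if top:
            return body
        return f"{body}:{n.length:.10g}"

    return fmt(tree.root, True) + ";"


def write_newick(tree: Tree, path: str, include_support: bool = True) -> None:
    """Serialize a tree to newick with branch lengths and support labels."""
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree, include_support=include_support) + "\n")


def read_newick(path_or_string: str, from_string: bool = False) -> Tree:
    """Parse newick (via dendropy) into the package's Tree representation."""
    if from_string:
        dt = dendropy.Tree.get(data=path_or_string, schema="newick")
    else:
        dt = dendropy.Tree.get(path=path_or_string, schema="newick")

    def convert(dn) -> TreeNode:
        node = TreeNode(
            label=dn.taxon.label.replace(" ", "_") if dn.taxon else None,
            length=dn.edge.length if dn.edge.length is not None else 0.0,
        )
        if dn.label is not None and not dn.is_leaf():
            try:
                node.support = float(dn.label)
            except ValueError:
                pass
        node.children = [convert(c) for c in dn.child_nodes()]
        return node

    return Tree(root=convert(dt.seed_node))


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_tsv_matrix(path: str):
    """Read a TSV with a header row and a row-label first column (pandas)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df, path: str) -> None:
    df.to_csv(path, sep="\t")
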