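"""Promoter extraction, IUPAC motif scanning and binomial overrepresentation.

The analysis asks whether a cis-regulatory motif occurs in a group of genes
(e.g. the family members highly expressed in one tissue) more often than in
the genome-wide background of all protein-coding genes.  Presence/absence of
each motif in the 2-kb upstream promoter enters a one-sample exact binomial
proportion test against the background prevalence; an exact tail is used
rather than a normal approximation because the tissue groups can be very
small (a handful of genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io_core import GeneModel, GenomeSequence, log, reverse_complement

DEFAULT_PROMOTER_LENGTH = 2000  # nt of upstream sequence
DEFAULT_ALPHA = 0.05

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGTN"),
}
# An N in the genome is unknown sequence: it matches only the motif letter N.

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(motif: str) -> str:
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC consensus motif from a catalog such as PLACE/PlantCARE."""

    motif_id: str
    iupac: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", self.iupac.upper())
        if len(self.iupac) < 4:
            raise ValueError(f"motif {self.motif_id!r}: shorter than 4 nt")
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.motif_id!r}: invalid IUPAC letters {sorted(bad)}")


def read_motif_catalog(path: str) -> list[MotifPattern]:
    """Read a TSV motif catalog with columns motif_id, iupac[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return [MotifPattern(row[cols[0]], row[cols[1]],
                         row[cols[2]] if len(cols) > 2 else "")
            for _, row in df.iterrows()]


@dataclass
class PromoterSet:
    """Upstream sequences per gene, with the extraction length parameter."""

    sequences: dict[str, str]
    length: int = DEFAULT_PROMOTER_LENGTH
    clipped: set[str] = field(default_factory=set)
    bed: list[tuple[str, int, int, str, int, str]] = field(default_factory=list)


def extract_upstream(genome: Sequence[GenomeSequence],
                     gene_models: Sequence[GeneModel],
                     L: int = DEFAULT_PROMOTER_LENGTH) -> PromoterSet:
    """Extract up to L nt of upstream promoter sequence per gene, strand-aware.

    Plus strand: genome[max(0, tss-L), tss).  Minus strand: the reverse
    complement of genome[tss+1, min(contig_end, tss+1+L)).  Promoters clipped
    at the contig edge are flagged; genes with zero upstream sequence are
    excluded with a warning.  BED6 rows (0-based half-open, genomic strand)
    are kept alongside for audit.
    """
    contigs = {c.contig_id: c.sequence for c in genome}
    out = PromoterSet(sequences={}, length=L)
    for g in gene_models:
        if g.contig_id not in contigs:
            raise KeyError(f"gene {g.gene_id!r}: contig {g.contig_id!r} absent")
        seq = contigs[g.contig_id]
        if g.strand == "+":
            start, end = max(0, g.tss - L), g.tss
            promoter = seq[start:end]
        else:
            start, end = g.tss + 1, min(len(seq), g.tss + 1 + L)
            promoter = reverse_complement(seq[start:end])
        if not promoter:
            log.warning("gene %s: no upstream sequence at contig edge; skipped",
                        g.gene_id)
            continue
        out.sequences[g.gene_id] = promoter
        if len(promoter) < L:
            out.clipped.add(g.gene_id)
        out.bed.append((g.contig_id, start, end, g.gene_id, 0, g.strand))
    return out


@lru_cache(maxsize=4096)
def _compile_iupac(motif: str) -> "re.Pattern[str]":
    body = "".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in motif)
    return re.compile(f"(?=(?:{body}))")  # lookahead so overlaps all count


def count_motif(sequence: str, motif: str) -> int:
    """Occurrences of an IUPAC motif in a DNA string; overlaps counted."""
    return sum(1 for _ in _compile_iupac(motif).finditer(sequence))


@dataclass
class PresenceMatrix:
    """Genes x motifs occurrence counts; presence means count >= 1."""

    counts: pd.DataFrame  # genes x motifs, integer counts

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


def scan_motifs(promoters: PromoterSet, motifs: Iterable[MotifPattern],
                both_strands: bool = True) -> PresenceMatrix:
    """Count motif occurrences in every promoter.

    Counts are the number of match start positions of the expanded IUPAC
    pattern (overlapping matches all count); with both_strands the matches of
    the reverse-complement pattern are added, so scanning is symmetric under
    reverse-complementing the promoters.
    """
    motifs = list(motifs)
    gene_ids = list(promoters.sequences)
    data = np.zeros((len(gene_ids), len(motifs)), dtype=int)
    for j, motif in enumerate(motifs):
        patterns = [motif.iupac]
        if both_strands:
            rc = iupac_reverse_complement(motif.iupac)
            # a palindromic consensus would double-count if scanned twice
            if rc != motif.iupac:
                patterns.append(rc)
        for i, gid in enumerate(gene_ids):
            seq = promoters.sequences[gid]
            data[i, j] = sum(count_motif(seq, p) for p in patterns)
    counts = pd.DataFrame(data, index=gene_ids,
                          columns=[m.motif_id for m in motifs])
    return PresenceMatrix(counts=counts)


@dataclass
class EnrichmentResult:
    """One motif's one-sample binomial test of group prevalence vs background."""

    motif_id: str
    n: int  # group size
    x: int  # group genes carrying the motif
    p0: float  # background prevalence
    p_value: float
    q_value: float | None = None
    significant: bool = False
    note: str = ""


def exact_binomial_tail(x: int, n: int, p0: float,
                        alternative: str = "greater") -> tuple[float, str]:
    """Exact binomial p-value for x successes in n trials at background p0.

    'greater': p = sum_{k>=x} C(n,k) p0^k (1-p0)^(n-k).  Degenerate
    backgrounds are handled analytically: p0 = 0 with x > 0 cannot arise
    under the null, so p is 0 and the result is flagged 'background-absent';
    p0 = 1 makes any x <= n certain, p = 1.
    """
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    if p0 == 0.0:
        return (1.0, "") if x == 0 else (0.0, "background-absent")
    if p0 == 1.0:
        return 1.0, ""
    if alternative == "greater":
        return float(binom.sf(x - 1, n, p0)), ""
    if alternative == "two_sided":
        from scipy.stats import binomtest

        return float(binomtest(x, n, p0, alternative="two-sided").pvalue), ""
    raise ValueError(f"unknown alternative {alternative!r}")


def binomial_enrichment(presence: PresenceMatrix, group: set[str],
                        background: set[str],
                        alternative: str = "greater",
                        alpha: float = DEFAULT_ALPHA,
                        adjust: str = "BH") -> list[EnrichmentResult]:
    """Test every motif for overrepresentation in `group` vs `background`.

    The background prevalence p0 of each motif is the fraction of background
    genes whose promoter carries it at least once; the group success count x
    is compared to Binomial(n=|group|, p0) with an exact tail.
    """
    if not group:
        raise ValueError("empty group")
    if not group <= background:
        raise ValueError("group must be a subset of the background")
    pres = presence.presence
    group_l = sorted(group & set(pres.index))
    background_l = sorted(background & set(pres.index))
    if not group_l:
        raise ValueError("no group gene has a scanned promoter")
    results: list[EnrichmentResult] = []
    for motif_id in pres.columns:
        col = pres[motif_id]
        p0 = float(col.loc[background_l].mean())
        x = int(col.loc[group_l].sum())
        n = len(group_l)
        p, note = exact_binomial_tail(x, n, p0, alternative)
        results.append(EnrichmentResult(motif_id=motif_id, n=n, x=x, p0=p0,
                                        p_value=p, note=note))
    qs = adjust_pvalues([r.p_value for r in results], method=adjust)
    for r, q in zip(results, qs):
        r.q_value = q
        r.significant = r.p_value <= alpha
    return results


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or none."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    if method == "BH":
        if arr.size == 0:
            return []
        return list(multipletests(arr, method="fdr_bh")[1])
    raise ValueError(f"unknown method {method!r}")


def tissue_motif_report(enrichments_by_tissue: dict[str, list[EnrichmentResult]],
                        presence: PresenceMatrix,
                        groups: dict[str, set[str]],
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Table of significant tissue/motif pairs with the member genes carrying it.

    Rows only for motifs significant at alpha in a tissue group; ordered by
    (tissue, q-value, motif_id).  The same motif may appear for several
    tissues.
    """
    pres = presence.presence
    rows = []
    for tissue in sorted(enrichments_by_tissue):
        for r in enrichments_by_tissue[tissue]:
            if r.p_value > alpha:
                continue
            members = sorted(g for g in groups[tissue]
                             if g in pres.index and pres.at[g, r.motif_id])
            rows.append({
                "tissue": tissue, "motif_id": r.motif_id,
                "x": r.x, "n": r.n, "p0": r.p0,
                "p_value": r.p_value, "q_value": r.q_value,
                "member_genes": ",".join(members),
            })
    df = pd.DataFrame(rows, columns=["tissue", "motif_id", "x", "n", "p0",
                                     "p_value", "q_value", "member_genes"])
    if not df.empty:
        df = df.sort_values(["tissue", "q_value", "motif_id"],
                            kind="mergesort").reset_index(drop=True)
    return df
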