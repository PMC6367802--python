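"""Synthetic genomes, proteins, promoters, alignments and expression tables.

Every pipeline stage can be exercised without downloads: each generator here
emits data with a machine-readable ground truth so that downstream calls
(family mining, intron-site clustering, motif enrichment, specificity
calling) can be scored against what was planted.

The defaults emulate the study conditions of a plant multigene-family
survey: ~300 candidate proteins of which 233 are true family members of
450-600 aa carrying all four P450 signature motifs; gene models with 0-14
introns concentrated at one or two introns and two heavily-shared same-phase
conserved insertion sites; 2-kb promoters of i.i.d. uniform composition with
group-elevated motif planting; and log-normal FPKM over 19 tissues with a
designated-tissue fold factor for the tissue-specific genes.

All randomness flows from `SimulationConfig.seed`; the same seed reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_profiling import ExpressionMatrix
from .family_mining import (AlignmentBlock, DEFAULT_PROFILES, SignatureProfile,
                            scan_signatures)
from .io_core import (AMINO_ACIDS, GeneModel, GenomeSequence, ProteinRecord,
                      Tree, TreeNode, reverse_complement)
from .promoter_enrichment import (IUPAC, MotifPattern, PromoterSet,
                                  iupac_reverse_complement)

#: Paper-scale intron-count distribution (concentrated at 1-2 introns).
DEFAULT_INTRON_WEIGHTS = {
    "0": 23 / 233, "1": 108 / 233, "2": 37 / 233,
    "3": 4 / 233, "4": 30 / 233, "5+": 31 / 233,
}

DEFAULT_TISSUES = (
    "leaf", "root", "buds", "petals", "stem", "flower",
    "peel_IG", "peel_MG", "peel_Br", "peel_Or", "peel_R",
    "flesh_IG", "flesh_MG", "flesh_Br", "flesh_Or", "flesh_R",
    "seeds_MG", "seeds_Or", "seeds_R",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the seed fully determines all outputs."""

    seed: int
    n_genes: int = 300
    n_true_family: int = 233
    intron_count_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_WEIGHTS))
    #: (mean aa position, phase, jitter); jitter must stay within the
    #: conservation window used downstream (<= window/2 guarantees exact
    #: single-linkage recovery)
    conserved_sites: list[tuple[float, int, float]] = field(
        default_factory=lambda: [(120.0, 1, 10.0), (280.0, 1, 10.0)])
    promoter_length: int = 2000
    motif_catalog_size: int = 946
    #: (motif id, background rate p0, group rate p1)
    planted_motifs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("M0001", 0.1, 0.9)])
    group_size: int = 10
    n_tissues: int = 19
    specific_fraction: float = 0.31
    fpkm_lognormal_params: tuple[float, float] = (-1.33, 0.6)
    specific_fold: float = 100.0
    min_protein_len: int = 450
    max_protein_len: int = 600

    def __post_init__(self) -> None:
        w = sum(self.intron_count_weights.values())
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("intron_count_weights must sum to 1")
        if not 0 <= self.specific_fraction <= 1:
            raise ValueError("specific_fraction must be in [0,1]")
        for mid, p0, p1 in self.planted_motifs:
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"motif {mid}: rates outside [0,1]")
            if p1 < p0:
                raise ValueError(f"motif {mid}: p1 < p0 for an enriched motif")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent, reproducible generator per output stream."""
        return np.random.default_rng([self.seed, stream])


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Gene models with planted intron sites
# ---------------------------------------------------------------------------

_INTRON_CLASSES = ("0", "1", "2", "3", "4", "5+")
_PHASE_WEIGHTS = (0.2, 0.6, 0.2)  # phase 1 dominates, as in plant P450 genes


def _make_site_catalog(config: SimulationConfig, window: float,
                       rng: np.random.Generator,
                       ) -> list[tuple[float, int, float, bool]]:
    """Conserved sites plus well-separated background sites.

    Same-phase site means are kept > window + 2*jitter apart so that
    single-linkage clustering at the window recovers exactly the planted
    sites.  Returns (mean, phase, jitter, is_conserved_site) tuples.
    """
    max_pos = config.min_protein_len - 10.0
    sites: list[tuple[float, int, float, bool]] = []
    for mean, phase, jitter in config.conserved_sites:
        if mean + jitter >= config.min_protein_len:
            raise ValueError(
                f"requested intron position {mean} (+jitter {jitter}) beyond "
                f"the minimum protein length {config.min_protein_len}")
        sites.append((float(mean), int(phase), float(jitter), True))
    jitter_bg = 10.0
    sep = window + 2 * jitter_bg + 1
    attempts = 0
    while len(sites) < 20 and attempts < 4000:
        attempts += 1
        mean = float(rng.uniform(10.0, max_pos))
        phase = int(rng.choice(3, p=_PHASE_WEIGHTS))
        if all(abs(mean - m) > sep for m, ph, _, _ in sites if ph == phase):
            sites.append((mean, phase, jitter_bg, False))
    sites.sort(key=lambda s: s[0])
    return sites


def simulate_gene_models(config: SimulationConfig, window: float = 45.0,
                         ) -> tuple[list[GenomeSequence], list[GeneModel],
                                    pd.DataFrame]:
    """Genomes and gene models with known intron positions and phases.

    Every gene sits on its own contig with a 2.1-kb upstream flank (so
    promoter extraction is never clipped).  Intron counts follow the
    configured class weights; a gene's introns are drawn from a catalog of
    insertion sites — the configured conserved sites (one of which is carried
    by nearly every intron-bearing gene, emulating the dominant shared site
    of real intron maps) plus well-separated background sites — and realised
    with per-site jitter.  The ground-truth table lists
    (gene_id, site_id, aa_position, phase, conserved_site) for every intron.
    """
    rng = config.rng(1)
    catalog = _make_site_catalog(config, window, rng)
    site_ids = [f"S{i:02d}" for i in range(1, len(catalog) + 1)]
    conserved_idx = [i for i, s in enumerate(catalog) if s[3]]

    classes = list(config.intron_count_weights)
    weights = np.array([config.intron_count_weights[c] for c in classes])

    genomes: list[GenomeSequence] = []
    models: list[GeneModel] = []
    truth_rows: list[dict] = []
    bases = np.array(list("ACGT"))
    for gid in _gene_ids(config.n_genes):
        plen = int(rng.integers(config.min_protein_len,
                                config.max_protein_len + 1))
        cls = classes[int(rng.choice(len(classes), p=weights))]
        n_introns = (int(cls) if cls != "5+"
                     else int(5 + rng.integers(0, 10)))  # up to 14
        n_introns = min(n_introns, len(catalog))

        chosen: list[int] = []
        if n_introns >= 1 and conserved_idx:
            # carry one of the conserved sites, heavily biased to the first
            pick = conserved_idx[0] if rng.random() < 0.84 else conserved_idx[-1]
            chosen.append(pick)
        remaining = [i for i in range(len(catalog)) if i not in chosen]
        extra = rng.choice(len(remaining), size=n_introns - len(chosen),
                           replace=False)
        chosen.extend(remaining[int(e)] for e in extra)

        ks: list[tuple[int, int]] = []  # (k, catalog index)
        for ci in sorted(chosen, key=lambda i: catalog[i][0]):
            mean, phase, jitter, _ = catalog[ci]
            aa = int(round(mean + rng.uniform(-jitter, jitter)))
            aa = max(2, min(plen - 1, aa))
            k = (aa - 1) * 3 + phase
            ks.append((k, ci))
        ks.sort()

        cds_len = 3 * plen
        cds_seq = "".join(rng.choice(bases, size=cds_len))
        pieces: list[str] = []
        exon_lens: list[int] = []
        prev = 0
        for k, ci in ks:
            exon_lens.append(k - prev)
            prev = k
            aa, phase = k // 3 + 1, k % 3
            truth_rows.append({"gene_id": gid, "site_id": site_ids[ci],
                               "aa_position": aa, "phase": phase,
                               "conserved_site": catalog[ci][3]})
        exon_lens.append(cds_len - prev)

        intron_seqs = ["".join(rng.choice(bases, size=int(rng.integers(80, 500))))
                       for _ in ks]
        body_parts: list[str] = []
        pos = 0
        exon_ivs_t: list[tuple[int, int]] = []  # transcript-body coordinates
        for i, elen in enumerate(exon_lens):
            body_parts.append(cds_seq[sum(exon_lens[:i]):sum(exon_lens[:i + 1])])
            exon_ivs_t.append((pos, pos + elen))
            pos += elen
            if i < len(intron_seqs):
                body_parts.append(intron_seqs[i])
                pos += len(intron_seqs[i])
        body = "".join(body_parts)

        strand = "+" if rng.random() < 0.5 else "-"
        up = "".join(rng.choice(bases, size=config.promoter_length + 100))
        down = "".join(rng.choice(bases, size=100))
        if strand == "+":
            contig_seq = up + body + down
            off = len(up)
            exons = [(off + s, off + e) for s, e in exon_ivs_t]
        else:
            contig_seq = down + reverse_complement(body) + up
            off = len(down)
            exons = [(off + len(body) - e, off + len(body) - s)
                     for s, e in exon_ivs_t]
            exons.sort()
        contig = f"ctg_{gid}"
        genomes.append(GenomeSequence(contig, contig_seq))
        models.append(GeneModel(gene_id=gid, contig_id=contig, strand=strand,
                                exons=exons, cds=list(exons)))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "site_id", "aa_position", "phase",
                             "conserved_site"])
    return genomes, models, truth


# ---------------------------------------------------------------------------
# Proteins with signature motifs
# ---------------------------------------------------------------------------

def _instantiate_profile(profile: SignatureProfile,
                         rng: np.random.Generator) -> str:
    return "".join(
        sorted(allowed)[int(rng.integers(0, len(allowed)))]
        for allowed in profile.positions())


def _plant(seq: list[str], motif: str, taken: list[tuple[int, int]],
           rng: np.random.Generator) -> None:
    for _ in range(200):
        start = int(rng.integers(0, len(seq) - len(motif) + 1))
        span = (start, start + len(motif))
        if all(span[1] <= s or span[0] >= e for s, e in taken):
            seq[span[0]:span[1]] = list(motif)
            taken.append(span)
            return
    raise RuntimeError("could not place motif without overlap")


def simulate_protein_set(config: SimulationConfig,
                         profiles: tuple[SignatureProfile, ...] = DEFAULT_PROFILES,
                         ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteins with truth labels: true family members plus labelled decoys.

    True members: length uniform in [450,600] with all four signature motifs
    planted at non-overlapping positions.  Decoys alternate between a protein
    scrubbed of one motif and a length violator; the defect is recorded.
    """
    rng = config.rng(2)
    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    rows: list[dict] = []

    def random_protein(length: int, plant_profiles) -> str:
        seq = list("".join(rng.choice(aa, size=length)))
        taken: list[tuple[int, int]] = []
        for prof in plant_profiles:
            _plant(seq, _instantiate_profile(prof, rng), taken, rng)
        return "".join(seq)

    for i in range(config.n_true_family):
        pid = f"p{i + 1:04d}"
        length = int(rng.integers(config.min_protein_len,
                                  config.max_protein_len + 1))
        records.append(ProteinRecord(pid, random_protein(length, profiles)))
        rows.append({"protein_id": pid, "is_family": True, "defect": ""})

    n_decoys = config.n_genes - config.n_true_family
    for i in range(n_decoys):
        pid = f"d{i + 1:04d}"
        if i % 2 == 0:
            # scrub one motif, keep the other three
            missing = profiles[i // 2 % len(profiles)]
            keep = tuple(p for p in profiles if p.name != missing.name)
            positions = missing.positions()
            for _ in range(100):
                length = int(rng.integers(config.min_protein_len,
                                          config.max_protein_len + 1))
                seq = list(random_protein(length, keep))
                for _ in range(50):
                    hits = scan_signatures(ProteinRecord(pid, "".join(seq)),
                                           (missing,))[missing.name]
                    if not hits:
                        break
                    # break the leftmost match at its most constrained position
                    h = hits[0]
                    j = min(range(len(positions)),
                            key=lambda jj: len(positions[jj]))
                    forbidden = positions[j]
                    choices = [c for c in AMINO_ACIDS if c not in forbidden]
                    seq[h + j] = choices[int(rng.integers(0, len(choices)))]
                final = ProteinRecord(pid, "".join(seq))
                got = scan_signatures(final, profiles)
                if not got[missing.name] and all(
                        got[p.name] for p in keep):
                    records.append(final)
                    rows.append({"protein_id": pid, "is_family": False,
                                 "defect": f"missing_{missing.name}"})
                    break
            else:
                raise RuntimeError("decoy scrubbing failed to converge")
        else:
            length = 300 if i % 4 == 1 else 700
            records.append(ProteinRecord(pid, random_protein(length, profiles)))
            rows.append({"protein_id": pid, "is_family": False,
                         "defect": "length"})
    truth = pd.DataFrame(rows, columns=["protein_id", "is_family", "defect"])
    return records, truth


# ---------------------------------------------------------------------------
# Motif catalog and promoters
# ---------------------------------------------------------------------------

_CATALOG_LETTERS = list("ACGT") + list("RYSWKM")
_CATALOG_PROBS = [0.2] * 4 + [1.0 / 30] * 6  # mostly fixed bases


def simulate_motif_catalog(config: SimulationConfig) -> list[MotifPattern]:
    """A catalog of random IUPAC consensus motifs (lengths 6-10)."""
    rng = config.rng(3)
    motifs = []
    for i in range(config.motif_catalog_size):
        length = int(rng.integers(6, 11))
        letters = rng.choice(_CATALOG_LETTERS, size=length, p=_CATALOG_PROBS)
        motifs.append(MotifPattern(f"M{i + 1:04d}", "".join(letters),
                                   source="synthetic"))
    return motifs


def random_occurrence_probability(motif: str, promoter_length: int,
                                  both_strands: bool = True) -> float:
    """Expected-count upper bound on the chance a random promoter contains
    the motif, under i.i.d. uniform A/C/G/T composition.

    Per start position the match probability is prod(|allowed|/4); with
    (L - m + 1) starts per strand the presence probability is bounded by the
    expected count (and well approximated by 1 - exp(-E) for rare motifs).
    """
    per_pos = 1.0
    for c in motif:
        per_pos *= len(IUPAC[c] - {"N"}) / 4.0
    starts = promoter_length - len(motif) + 1
    n_patterns = 1
    if both_strands and iupac_reverse_complement(motif) != motif:
        n_patterns = 2
    expected = n_patterns * starts * per_pos
    return 1.0 - math.exp(-expected)


def simulate_promoters(config: SimulationConfig,
                       gene_ids: list[str],
                       motifs: list[MotifPattern],
                       group: set[str] | None = None,
                       ) -> tuple[PromoterSet, pd.DataFrame]:
    """Promoters of i.i.d. uniform composition with Bernoulli motif planting.

    For each configured (motif, p0, p1): every gene independently receives
    one planted occurrence with probability p1 (group genes) or p0
    (background genes), inserted at a uniform position on a uniform strand.
    Plants never overlap each other (overlaps are re-drawn), so the planted
    truth is exact.  Group defaults to the first `group_size` genes.
    """
    rng = config.rng(4)
    L = config.promoter_length
    by_id = {m.motif_id: m for m in motifs}
    for mid, _, _ in config.planted_motifs:
        if len(by_id[mid].iupac) > L:
            raise ValueError(f"motif {mid} longer than the promoter")
    if group is None:
        group = set(gene_ids[:config.group_size])
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    rows: list[dict] = []
    for gid in gene_ids:
        seq = list("".join(rng.choice(bases, size=L)))
        taken: list[tuple[int, int]] = []
        for mid, p0, p1 in config.planted_motifs:
            rate = p1 if gid in group else p0
            if rng.random() >= rate:
                rows.append({"gene_id": gid, "motif_id": mid, "planted": False,
                             "position": -1, "strand": "."})
                continue
            pat = by_id[mid].iupac
            concrete = "".join(
                sorted(IUPAC[c] - {"N"})[int(rng.integers(0, len(IUPAC[c] - {"N"})))]
                for c in pat)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = concrete if strand == "+" else reverse_complement(concrete)
            for _ in range(200):
                start = int(rng.integers(0, L - len(inserted) + 1))
                span = (start, start + len(inserted))
                if all(span[1] <= s or span[0] >= e for s, e in taken):
                    seq[span[0]:span[1]] = list(inserted)
                    taken.append(span)
                    rows.append({"gene_id": gid, "motif_id": mid,
                                 "planted": True, "position": start,
                                 "strand": strand})
                    break
            else:
                raise RuntimeError("could not place motif without overlap")
        sequences[gid] = "".join(seq)
    truth = pd.DataFrame(rows, columns=["gene_id", "motif_id", "planted",
                                        "position", "strand"])
    return PromoterSet(sequences=sequences, length=L), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig,
                        gene_ids: list[str] | None = None,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal FPKM with designated tissue-specific genes.

    Non-specific genes draw i.i.d. log-normal FPKM per tissue; a configured
    fraction of genes is tissue-specific: one designated tissue's value is
    multiplied by `specific_fold`.  The truth table records which genes are
    specific and to which tissue.
    """
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = config.rng(5)
    if gene_ids is None:
        gene_ids = _gene_ids(config.n_true_family)
    tissues = (list(DEFAULT_TISSUES[:config.n_tissues])
               if config.n_tissues <= len(DEFAULT_TISSUES)
               else [f"tissue_{i:02d}" for i in range(1, config.n_tissues + 1)])
    mu, sigma = config.fpkm_lognormal_params
    n = len(gene_ids)
    data = rng.lognormal(mean=mu, sigma=sigma, size=(n, config.n_tissues))
    n_specific = int(round(config.specific_fraction * n))
    specific_idx = rng.choice(n, size=n_specific, replace=False)
    rows = []
    designated = {}
    for gi in specific_idx:
        ti = int(rng.integers(0, config.n_tissues))
        data[gi, ti] *= config.specific_fold
        designated[gi] = ti
    for gi, gid in enumerate(gene_ids):
        rows.append({"gene_id": gid, "specific": gi in designated,
                     "tissue": tissues[designated[gi]] if gi in designated
                     else ""})
    matrix = ExpressionMatrix(pd.DataFrame(data, index=gene_ids,
                                           columns=tissues))
    truth = pd.DataFrame(rows, columns=["gene_id", "specific", "tissue"])
    return matrix, truth


# ---------------------------------------------------------------------------
# Alignments evolved on a tree
# ---------------------------------------------------------------------------

def simulate_alignment_on_tree(tree: Tree, length: int,
                               seed: int = 0) -> AlignmentBlock:
    """Evolve a gap-free protein alignment down a tree.

    The root sequence is i.i.d. uniform over the 20 amino acids; along each
    branch of length t, each site independently substitutes with probability
    1 - exp(-t) to a uniformly chosen different residue.  Leaf sequences are
    returned as an (ungapped) alignment block.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, 20, size=length)
    leaves: list[ProteinRecord] = []

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf():
            leaves.append(ProteinRecord(node.label, "".join(aa[seq])))
            return
        for child in node.children:
            p_sub = 1.0 - math.exp(-child.length)
            child_seq = seq.copy()
            hit = rng.random(length) < p_sub
            if hit.any():
                shift = rng.integers(1, 20, size=int(hit.sum()))
                child_seq[hit] = (child_seq[hit] + shift) % 20
            walk(child, child_seq)

    walk(tree.root, root_seq)
    return AlignmentBlock(leaves)


def random_tree(n_leaves: int, rng: np.random.Generator,
                min_branch: float = 0.05, max_branch: float = 0.4) -> Tree:
    """A random binary topology with uniform branch lengths (for oracles)."""
    nodes = [TreeNode(label=f"t{i + 1}",
                      length=float(rng.uniform(min_branch, max_branch)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = TreeNode(children=[b, a],
                          length=float(rng.uniform(min_branch, max_branch)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return Tree(root=TreeNode(children=nodes))


def tree_distance_matrix(tree: Tree):
    """Additive (path-length) distance matrix of a tree, for NJ oracles."""
    from .family_mining import DistanceMatrix

    labels = sorted(tree.leaf_labels())
    paths = tree.path_lengths()
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = paths[tuple(sorted((labels[i], labels[j])))]
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, kind="additive")
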