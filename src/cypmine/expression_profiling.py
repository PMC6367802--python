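"""FPKM expression profiling and qPCR relative quantification.

A gene is called expressed when its maximum FPKM across tissues reaches a
threshold T (default 2.0); tissue specificity is scored as
s = max-tissue FPKM / total FPKM, and a gene is tissue-specific when it is
expressed and s reaches a cutoff (default 0.5).  Heatmap preparation follows
the common ln(x+1) transform plus per-row unit-variance scaling.  qPCR fold
changes use the Livak 2^-ddCt method against a reference gene and a
calibrator tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import percent

DEFAULT_EXPRESSED_FPKM = 2.0
DEFAULT_SPECIFICITY_CUTOFF = 0.5


@dataclass
class ExpressionMatrix:
    """Genes x tissues FPKM matrix (non-negative, finite, >= 2 tissues)."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fpkm.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 tissues")
        vals = self.fpkm.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("FPKM values must be finite")
        if (vals < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class TissueCall:
    """Expression and tissue-specificity call for one gene."""

    gene_id: str
    expressed: bool
    top_tissue: str
    specificity: float  # max FPKM / total FPKM, 0 when the row is all zero
    specific: bool


def call_expressed(m: ExpressionMatrix, T: float = DEFAULT_EXPRESSED_FPKM,
                   ) -> tuple[set[str], dict[str, float | int]]:
    """Genes whose maximum tissue FPKM reaches T, with a proportion summary.

    The summary reports the expressed count and its percentage of the input
    genes (two decimals, half-up rounding).
    """
    if T < 0:
        raise ValueError("threshold must be >= 0")
    maxima = m.fpkm.max(axis=1)
    expressed = set(maxima.index[maxima >= T])
    summary = {
        "n_genes": len(m.genes),
        "n_expressed": len(expressed),
        "pct_expressed": percent(len(expressed), len(m.genes)),
    }
    return expressed, summary


def tissue_specificity(m: ExpressionMatrix,
                       s_star: float = DEFAULT_SPECIFICITY_CUTOFF,
                       T: float = DEFAULT_EXPRESSED_FPKM) -> list[TissueCall]:
    """Score every gene's tissue specificity and call the specific ones.

    s = max FPKM / total FPKM lies in [1/n_tissues, 1] for any non-zero row
    (0 for an all-zero row); ties for the top tissue break by column order.
    specific requires both expressed (max >= T) and s >= s_star, so a
    specific gene is always an expressed gene.
    """
    expressed, _ = call_expressed(m, T)
    calls: list[TissueCall] = []
    for gene in m.genes:
        row = m.fpkm.loc[gene]
        total = float(row.sum())
        top = str(row.idxmax())  # first column on ties
        s = float(row.max()) / total if total > 0 else 0.0
        is_expr = gene in expressed
        calls.append(TissueCall(
            gene_id=gene, expressed=is_expr, top_tissue=top,
            specificity=s, specific=is_expr and s >= s_star,
        ))
    return calls


def specific_gene_groups(calls: list[TissueCall]) -> dict[str, set[str]]:
    """Tissue -> set of genes called specific to it (feeds enrichment groups)."""
    groups: dict[str, set[str]] = {}
    for c in calls:
        if c.specific:
            groups.setdefault(c.top_tissue, set()).add(c.gene_id)
    return groups


def heatmap_matrix(m: ExpressionMatrix, transform: str = "ln1p",
                   row_scaling: str = "unit_variance",
                   ) -> tuple[pd.DataFrame, set[str]]:
    """Prepare the matrix for heatmap display.

    Optional ln(x+1) transform, then per-row mean-centering with
    unit-variance scaling (ddof=1).  Constant rows have undefined variance:
    they are centered to zero and returned in the flagged set.
    """
    if transform not in ("ln1p", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if row_scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown row_scaling {row_scaling!r}")
    data = m.fpkm.to_numpy(dtype=float).copy()
    if transform == "ln1p":
        data = np.log1p(data)
    flagged: set[str] = set()
    if row_scaling == "unit_variance":
        means = data.mean(axis=1, keepdims=True)
        sds = data.std(axis=1, ddof=1, keepdims=True)
        data = data - means
        for i, gene in enumerate(m.genes):
            if sds[i, 0] > 0:
                data[i] /= sds[i, 0]
            else:
                flagged.add(gene)
    return pd.DataFrame(data, index=m.fpkm.index, columns=m.fpkm.columns), flagged


# ---------------------------------------------------------------------------
# qPCR (Livak 2^-ddCt)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene Ct in one sample."""

    gene: str
    tissue: str
    ct_target: float
    ct_reference: float
    replicate: int = 1  # biological replicate index

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target),
                        ("ct_reference", self.ct_reference)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.gene}/{self.tissue}: bad {name} {v}")


def ddct_fold_change(records: list[QpcrRecord], calibrator: str,
                     ) -> pd.DataFrame:
    """Relative expression by the Livak 2^-ddCt method.

    For each gene and tissue, dCt = Ct_target - Ct_reference (technical
    replicate Ct values are supplied already averaged; biological replicates
    carry distinct `replicate` indices).  ddCt subtracts the gene's
    calibrator-tissue dCt, matched within biological replicate when the
    calibrator was measured in that replicate, otherwise against the
    calibrator's mean dCt.  The fold change is 2^-ddCt; the table reports the
    per-tissue mean and sd of the fold over biological replicates.
    """
    by_gene: dict[str, list[QpcrRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    rows = []
    for gene, recs in sorted(by_gene.items()):
        dct: dict[tuple[str, int], float] = {}
        for r in recs:
            dct[(r.tissue, r.replicate)] = r.ct_target - r.ct_reference
        cal = [v for (t, _), v in dct.items() if t == calibrator]
        if not cal:
            raise ValueError(f"gene {gene!r}: no calibrator tissue "
                             f"{calibrator!r} measurement")
        cal_by_rep = {rep: v for (t, rep), v in dct.items() if t == calibrator}
        cal_mean = float(np.mean(cal))
        folds: dict[str, list[float]] = {}
        for (tissue, rep), v in dct.items():
            ddct = v - cal_by_rep.get(rep, cal_mean)
            folds.setdefault(tissue, []).append(2.0 ** (-ddct))
        for tissue, ff in sorted(folds.items()):
            rows.append({
                "gene": gene, "tissue": tissue,
                "fold_mean": float(np.mean(ff)),
                "fold_sd": float(np.std(ff, ddof=1)) if len(ff) > 1 else 0.0,
                "n_replicates": len(ff),
            })
    return pd.DataFrame(rows, columns=["gene", "tissue", "fold_mean",
                                       "fold_sd", "n_replicates"])


def read_ct_table(path: str) -> list[QpcrRecord]:
    """Read a qPCR Ct TSV with columns gene, tissue, ct_target, ct_reference
    and an optional replicate column."""
    df = pd.read_csv(path, sep="\t")
    has_rep = "replicate" in df.columns
    return [QpcrRecord(gene=str(r.gene), tissue=str(r.tissue),
                       ct_target=float(r.ct_target),
                       ct_reference=float(r.ct_reference),
                       replicate=int(r.replicate) if has_rep else 1)
            for r in df.itertuples()]
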