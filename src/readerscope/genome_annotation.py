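"""Relating enriched islands and tag signal to gene models.

Genes carry a 2-kb strand-aware promoter immediately upstream of the TSS;
a gene is bound by a reader protein when an island overlaps its promoter
by at least one base.  Islands are classified promoter / gene body /
intergenic (promoter wins over body when an island spans both), promoters
are ranked by a Poisson binding p-value against the control, genes are
stratified into high/medium/silent expression tertiles (30/40/30) by
RPKM, and per-class metagene profiles are computed over 2-kb flanks plus
a length-normalized gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .chipseq_signal import DEPTH_TARGET, TagSet

__all__ = [
    "GeneRecord",
    "read_genes_bed12",
    "read_genes_gtf",
    "promoter_region",
    "classify_islands",
    "promoter_bound",
    "rank_promoters",
    "combinatorial_patterns",
    "rpkm",
    "expression_classes",
    "metagene_profile",
    "knockdown_response",
]

PROMOTER_BP = 2000
FLANK_BP = 2000
FLANK_WINDOW = 100
DEFAULT_BODY_BINS = 40


@dataclass
class GeneRecord:
    """A gene model (0-based half-open body span) with expression annotations."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    rpkm: float = float("nan")
    expression_class: str = ""

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        """RPKM length: exonic if exons are given, else the genomic span."""
        if self.exons:
            return sum(e - s for s, e in self.exons)
        return self.end - self.start

    @property
    def expressed(self) -> bool:
        return self.rpkm >= 1.0


def read_genes_bed12(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        if len(row) >= 12:
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
            exons = [
                (int(row[1]) + s, int(row[1]) + s + sz)
                for s, sz in zip(starts, sizes)
            ]
        genes.append(
            GeneRecord(
                id=str(row[3]),
                chrom=str(row[0]),
                strand=str(row[5]),
                start=int(row[1]),
                end=int(row[2]),
                exons=exons,
            )
        )
    return genes


def read_genes_gtf(path) -> list[GeneRecord]:
    """Gene records from a GTF via gffutils (gene + exon features)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneRecord(
                id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
            )
        )
    return genes


def promoter_region(
    gene: GeneRecord, chrom_size: int | None = None
) -> tuple[int, int]:
    """The 2-kb region immediately upstream of the TSS, strand-aware, clamped."""
    if gene.strand == "+":
        lo, hi = gene.tss - PROMOTER_BP, gene.tss
    else:
        lo, hi = gene.tss, gene.tss + PROMOTER_BP
    lo = max(0, lo)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return (lo, hi)


def _annotation_trees(
    genes: list[GeneRecord],
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    promoters: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = promoter_region(g)
        if hi > lo:
            promoters.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.id)
        if g.end > g.start:
            bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.id)
    return promoters, bodies


def classify_islands(islands, genes: list[GeneRecord]) -> pd.Series:
    """Fractions of islands in promoter / gene body / intergenic categories.

    Each island gets a single category with priority promoter > gene body >
    intergenic; islands on chromosomes absent from the annotation count as
    intergenic (with a warning).
    """
    promoters, bodies = _annotation_trees(genes)
    known = set(promoters) | set(bodies)
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    for isl in islands:
        if isl.chrom not in known:
            warnings.warn(f"island chromosome {isl.chrom!r} not in annotation")
            counts["intergenic"] += 1
            continue
        if isl.chrom in promoters and promoters[isl.chrom].overlap(isl.start, isl.end):
            counts["promoter"] += 1
        elif isl.chrom in bodies and bodies[isl.chrom].overlap(isl.start, isl.end):
            counts["gene_body"] += 1
        else:
            counts["intergenic"] += 1
    total = max(1, len(list(islands)))
    return pd.Series({k: v / total for k, v in counts.items()})


def promoter_bound(gene: GeneRecord, islands) -> bool:
    """True iff any island overlaps the gene's promoter by >= 1 bp."""
    lo, hi = promoter_region(gene)
    for isl in islands:
        if isl.chrom == gene.chrom and isl.start < hi and isl.end > lo:
            return True
    return False


def _interval_count(tagset: TagSet, chrom: str, lo: int, hi: int) -> int:
    pos = tagset.all_positions(chrom)
    return int(
        np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left")
    )


def rank_promoters(
    genes: list[GeneRecord],
    sample_tagset: TagSet,
    control_tagset: TagSet | None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Promoters ranked by Poisson binding p-value against the control.

    Expectation per promoter = control count scaled to sample depth, plus a
    pseudocount; ties broken by fold enrichment (descending) then gene id.
    """
    scale = 1.0
    if control_tagset is not None and control_tagset.library_size > 0:
        scale = sample_tagset.library_size / control_tagset.library_size
    rows = []
    for g in genes:
        lo, hi = promoter_region(g)
        s = _interval_count(sample_tagset, g.chrom, lo, hi)
        c = (
            _interval_count(control_tagset, g.chrom, lo, hi) * scale
            if control_tagset is not None
            else 0.0
        )
        lam = c + pseudocount
        p = float(stats.poisson.sf(s - 1, lam)) if s > 0 else 1.0
        rows.append(
            {
                "gene": g.id,
                "sample_count": s,
                "expected": lam,
                "fold": (s + pseudocount) / lam,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["p", "fold", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)


def combinatorial_patterns(
    binding: pd.DataFrame, expressed: pd.Series | None = None
) -> pd.DataFrame:
    """Group genes by their exact 5-protein promoter-binding pattern.

    ``binding`` is a boolean frame (genes x proteins, columns in display
    order).  Groups are ordered by member count descending (ties by the
    pattern string, most-bound first), except the all-unbound group which
    is forced last; genes within a group are ordered by id.
    """
    patterns = binding.astype(bool).apply(
        lambda row: "".join("1" if v else "0" for v in row), axis=1
    )
    groups = []
    for pat, idx in patterns.groupby(patterns).groups.items():
        gene_ids = sorted(str(i) for i in idx)
        groups.append((pat, gene_ids))
    all_unbound = "0" * binding.shape[1]
    groups.sort(key=lambda g: (g[0] == all_unbound, -len(g[1]), tuple(-int(c) for c in g[0])))
    rows = []
    for rank, (pat, gene_ids) in enumerate(groups, start=1):
        for gid in gene_ids:
            rows.append(
                {
                    "pattern": pat,
                    "group_rank": rank,
                    "group_size": len(gene_ids),
                    "gene": gid,
                    "expressed": bool(expressed[gid])
                    if expressed is not None
                    else None,
                }
            )
    return pd.DataFrame(rows)


def rpkm(
    gene_read_count: float, gene_length_bp: int, mapped_library_size: int
) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if mapped_library_size <= 0:
        raise ValueError("library size must be positive")
    return gene_read_count / (gene_length_bp / 1000 * mapped_library_size / 1e6)


def expression_classes(rpkm_by_gene: pd.Series) -> pd.Series:
    """30/40/30 split of the RPKM ranking into high / medium / silent.

    Top 30% (floor) high, bottom 30% (floor) silent, remainder medium; ties
    broken deterministically by gene id.
    """
    if len(rpkm_by_gene) < 10:
        raise ValueError("need at least 10 genes to stratify")
    order = sorted(
        rpkm_by_gene.index, key=lambda g: (-rpkm_by_gene[g], str(g))
    )
    n = len(order)
    n_high = int(0.3 * n)
    n_silent = int(0.3 * n)
    classes = {}
    for i, g in enumerate(order):
        if i < n_high:
            classes[g] = "high"
        elif i >= n - n_silent:
            classes[g] = "silent"
        else:
            classes[g] = "medium"
    return pd.Series(classes).reindex(rpkm_by_gene.index)


def _gene_profile(
    gene: GeneRecord,
    sample: TagSet,
    control: TagSet,
    sample_factor: float,
    control_factor: float,
    body_bins: int,
) -> np.ndarray | None:
    if gene.end - gene.start < body_bins:
        warnings.warn(f"gene {gene.id} shorter than one body bin; excluded")
        return None
    n_flank = FLANK_BP // FLANK_WINDOW
    up = np.arange(n_flank + 1) * FLANK_WINDOW + (gene.start - FLANK_BP)
    body = np.linspace(gene.start, gene.end, body_bins + 1)
    down = np.arange(n_flank + 1) * FLANK_WINDOW + gene.end
    edges = np.concatenate([up, body[1:-1], down])
    edges = np.clip(edges, 0, None)
    spos = sample.all_positions(gene.chrom)
    cpos = control.all_positions(gene.chrom)
    sc = np.diff(np.searchsorted(spos, edges))
    cc = np.diff(np.searchsorted(cpos, edges))
    widths = np.diff(edges)
    widths[widths == 0] = 1
    # density per 100 bp, depth-normalized, control-subtracted, clipped
    dens = np.maximum(
        0.0,
        sc / widths * FLANK_WINDOW * sample_factor
        - cc / widths * FLANK_WINDOW * control_factor,
    )
    if gene.strand == "-":
        dens = dens[::-1]
    return dens


def metagene_profile(
    sample_tagset: TagSet,
    control_tagset: TagSet,
    genes_by_class: dict[str, list[GeneRecord]],
    body_bins: int = DEFAULT_BODY_BINS,
) -> pd.DataFrame:
    """Mean control-subtracted read density per class over flank + body bins.

    Densities are per 100-bp window, normalized to 5 M reads per library;
    gene bodies are rescaled to ``body_bins`` equal-width bins; minus-strand
    genes are orientation-flipped before averaging.  Returns a frame with
    one row per class and 20 + body_bins + 20 bin columns.
    """
    sf = DEPTH_TARGET / max(1, sample_tagset.library_size)
    cf = DEPTH_TARGET / max(1, control_tagset.library_size)
    rows = {}
    for cls, genes in genes_by_class.items():
        profiles = [
            p
            for g in genes
            if (p := _gene_profile(g, sample_tagset, control_tagset, sf, cf, body_bins))
            is not None
        ]
        if not profiles:
            raise ValueError(f"no usable genes in class {cls!r}")
        rows[cls] = np.mean(profiles, axis=0)
    n_flank = FLANK_BP // FLANK_WINDOW
    cols = (
        [f"up{i}" for i in range(n_flank)]
        + [f"body{i}" for i in range(body_bins)]
        + [f"down{i}" for i in range(n_flank)]
    )
    return pd.DataFrame(rows, index=cols).T


def knockdown_response(
    ranked_bound_genes: list[str],
    expression_log2fc: pd.Series,
    fold_cutoff: float = 2.0,
) -> dict:
    """Expression response of the top promoter-bound genes to reader depletion.

    Returns each gene's log2 fold change plus the fractions of genes with at
    least ``fold_cutoff``-fold reduction / increase; genes missing from the
    fold-change table are reported, not silently dropped.
    """
    present = [g for g in ranked_bound_genes if g in expression_log2fc.index]
    missing = [g for g in ranked_bound_genes if g not in expression_log2fc.index]
    if not present:
        raise ValueError("no ranked gene appears in the fold-change table")
    fcs = expression_log2fc.loc[present]
    thr = np.log2(fold_cutoff)
    return {
        "log2_fc": fcs,
        "fraction_reduced": float((fcs <= -thr).mean()),
        "fraction_increased": float((fcs >= thr).mean()),
        "missing": missing,
    }
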