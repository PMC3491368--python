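"""Ground-truthed synthetic fixtures for every pipeline stage.

Two generators mirror the statistical structure of the study's inputs:

* spectra with planted proteoform mixtures -- Gaussian elution peaks at
  each isobaric group's precursor m/z, MS2 scans at the apex mixing the
  members' fragment templates in proportion to the planted abundances,
  multiplicative log-normal intensity noise;
* genomes with planted enrichment islands -- strand-split tags whose 5'
  positions sit 75 bp outside the fragment midpoints (so the shift step
  re-centers them), Poisson background, islands multiplying the local
  rate, plus per-gene expression levels spanning three well-separated
  tertiles and a knockdown response table.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ptm_chemistry import (
    IsobaricGroup,
    Proteoform,
    h4_tail_proteoforms,
    isobaric_groups,
    precursor_mz,
)
from .ms_quantification import PeakList, Scan

__all__ = [
    "SpectraScenario",
    "GenomeScenario",
    "PlantedIsland",
    "StudyFixture",
    "simulate_spectra",
    "simulate_chip_reads",
    "simulate_rnaseq",
    "simulate_rnaseq_reads",
    "h4_spectra_scenario",
    "make_study_fixture",
]

#: Default ChIP background tag rate (tags per bp per strand); 0.5 tags/kb.
DEFAULT_BACKGROUND = 0.0005
NUCLEOSOME_HALF = 75


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------


@dataclass
class SpectraScenario:
    """Planted proteoform mixture behind one LC-MS/MS run."""

    proteoforms: list[Proteoform]
    abundances: dict[str, float]  # form_id -> % of family, sums to 100
    apex_rt: float = 600.0  # s
    peak_width: float = 20.0  # Gaussian sigma, s
    rt_range: tuple[float, float] = (520.0, 680.0)
    scan_interval: float = 2.0  # s between MS1 scans
    charge: int = 2
    noise_sigma: float = 0.05  # multiplicative log-normal sigma (SNR ~ 20)
    baseline: float = 0.0  # additive intensity floor on MS1 peaks
    ms1_scale: float = 1e6  # intensity of a 100% form at the apex
    seed: int = 0


def h4_spectra_scenario(
    abundances: dict[str, float], seed: int = 0, noise_sigma: float = 0.05
) -> SpectraScenario:
    """Scenario over the 16 acetyl configurations of the H4 4-17 peptide."""
    forms = h4_tail_proteoforms()
    known = {p.form_id for p in forms}
    unknown = set(abundances) - known
    if unknown:
        raise ValueError(f"unknown form ids: {sorted(unknown)}")
    full = {p.form_id: abundances.get(p.form_id, 0.0) for p in forms}
    return SpectraScenario(
        proteoforms=forms, abundances=full, noise_sigma=noise_sigma, seed=seed
    )


def _noise(rng: np.random.Generator, sigma: float, size=None):
    if sigma <= 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_spectra(
    scenario: SpectraScenario,
) -> tuple[PeakList, pd.DataFrame, list[IsobaricGroup]]:
    """Realize a peak list plus its truth table.

    MS1 scans sample every isobaric group's precursor along a shared
    Gaussian elution profile (co-elution by construction); three MS2 scans
    straddle the apex for each multi-member group, mixing member fragment
    templates (uniform over b/y ions) proportionally to the planted
    abundances.
    """
    total = sum(scenario.abundances.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"abundances must sum to 100, got {total}")
    rng = np.random.default_rng(scenario.seed)
    groups = isobaric_groups(scenario.proteoforms)
    group_pct = [
        sum(scenario.abundances[m.form_id] for m in g.members) for g in groups
    ]
    lo, hi = scenario.rt_range
    rts = np.arange(lo, hi, scenario.scan_interval)
    scans: list[Scan] = []
    for t in rts:
        gauss = np.exp(-0.5 * ((t - scenario.apex_rt) / scenario.peak_width) ** 2)
        mzs, intens = [], []
        for g, pct in zip(groups, group_pct):
            if pct <= 0:
                continue
            height = scenario.ms1_scale * pct / 100.0 * gauss
            height = height * _noise(rng, scenario.noise_sigma, None)
            mzs.append(precursor_mz(g.mass, scenario.charge))
            intens.append(height + scenario.baseline)
        scans.append(
            Scan(rt=float(t), ms_level=1, mz=np.array(mzs), intensity=np.array(intens))
        )
    # MS2 scans around the apex for every group with >1 member
    ms2_offsets = (-scenario.scan_interval, 0.0, scenario.scan_interval)
    for g, pct in zip(groups, group_pct):
        if len(g.members) <= 1 or pct <= 0:
            continue
        prec = precursor_mz(g.mass, scenario.charge)
        for off in ms2_offsets:
            frag_mz, frag_int = [], []
            for member, frag in zip(g.members, g.fragments):
                share = scenario.abundances[member.form_id] / pct
                if share <= 0:
                    continue
                ions = frag.mz_values()
                per_ion = 1e5 * share / ions.size
                frag_mz.append(ions)
                frag_int.append(
                    per_ion * _noise(rng, scenario.noise_sigma, ions.size)
                )
            scans.append(
                Scan(
                    rt=scenario.apex_rt + off,
                    ms_level=2,
                    mz=np.concatenate(frag_mz),
                    intensity=np.concatenate(frag_int),
                    precursor_mz=prec,
                )
            )
    scans.sort(key=lambda s: (s.rt, s.ms_level))
    truth = pd.DataFrame(
        {
            "form": list(scenario.abundances),
            "true_pct": list(scenario.abundances.values()),
        }
    )
    return PeakList(scans), truth, groups


# --------------------------------------------------------------------------
# Genomes
# --------------------------------------------------------------------------


@dataclass
class PlantedIsland:
    chrom: str
    start: int
    end: int
    fold: float


@dataclass
class GenomeScenario:
    """Tag-generation model for one ChIP (or control) library."""

    chrom_sizes: dict[str, int]
    islands: list[PlantedIsland] = field(default_factory=list)
    background_rate: float = DEFAULT_BACKGROUND  # tags / bp / strand
    shift: int = NUCLEOSOME_HALF
    seed: int = 0


def simulate_chip_reads(
    scenario: GenomeScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tags (chrom, pos, strand) plus the truth island table.

    Fragment midpoints follow an inhomogeneous Poisson process whose rate
    is ``2 * background_rate`` multiplied by the island fold where planted;
    each midpoint becomes one tag on a random strand with its 5' position
    ``shift`` bp away, so the pipeline's shift step recovers the midpoint.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for chrom, size in scenario.chrom_sizes.items():
        isles = sorted(
            (i for i in scenario.islands if i.chrom == chrom),
            key=lambda i: i.start,
        )
        bounds = [0]
        folds = []
        cursor = 0
        for isl in isles:
            if isl.start < cursor:
                raise ValueError("planted islands must not overlap")
            if isl.start > cursor:
                bounds.append(isl.start)
                folds.append(1.0)
            bounds.append(isl.end)
            folds.append(isl.fold)
            cursor = isl.end
        if cursor < size:
            bounds.append(size)
            folds.append(1.0)
        for (a, b), fold in zip(zip(bounds, bounds[1:]), folds):
            rate = 2.0 * scenario.background_rate * fold
            n = rng.poisson(rate * (b - a))
            if n == 0:
                continue
            mids = rng.integers(a, b, size=n)
            fwd = rng.random(n) < 0.5
            pos = np.where(
                fwd, mids - scenario.shift, mids + scenario.shift
            ).astype(np.int64)
            pos = np.clip(pos, 0, size - 1)
            for p, f in zip(pos, fwd):
                rows.append((chrom, int(p), "+" if f else "-"))
    tags = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    truth = pd.DataFrame(
        [(i.chrom, i.start, i.end, i.fold) for i in scenario.islands],
        columns=["chrom", "start", "end", "fold"],
    )
    return tags, truth


def simulate_rnaseq(
    genes, true_rpkm: pd.Series, library_size: int, seed: int = 0
) -> pd.DataFrame:
    """Per-gene Poisson read counts with mean RPKM * length/1000 * library/1e6."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        mu = true_rpkm[g.id] * g.length / 1000 * library_size / 1e6
        rows.append({"gene": g.id, "count": int(rng.poisson(mu))})
    return pd.DataFrame(rows)


def simulate_rnaseq_reads(
    genes, counts: pd.DataFrame, read_length: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Read-level output (chrom, start, end) for the 20-bp center track."""
    rng = np.random.default_rng(seed)
    by_gene = dict(zip(counts["gene"], counts["count"]))
    rows = []
    for g in genes:
        n = by_gene.get(g.id, 0)
        if n == 0:
            continue
        hi = max(g.start + 1, g.end - read_length)
        starts = rng.integers(g.start, hi, size=n)
        for s in starts:
            rows.append((g.chrom, int(s), int(s) + read_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# --------------------------------------------------------------------------
# The miniature study
# --------------------------------------------------------------------------

ACTIVATORS = ("Brd2", "Brd3", "Brd4")
REPRESSORS = ("HP1a", "HP1b")
PROTEINS = ACTIVATORS + REPRESSORS

#: Degree-of-acetylation truth per sample type (un/mono/di/tri/tetra %),
#: shaped after the study's measured genomic, Brd-bound and HP1-bound H4.
ACETYL_TRUTH = {
    "input": (50.0, 35.0, 10.0, 4.5, 0.5),
    "activator": (20.0, 25.0, 20.0, 15.0, 20.0),
    "repressor": (70.0, 25.0, 4.0, 0.9, 0.1),
}

#: Within-acetyl-class weights: the single most abundant monoacetyl site
#: is K16, the rest spread evenly.
_MONO_W = {"K16": 0.7, "K5": 0.1, "K8": 0.1, "K12": 0.1}

#: Diacetyl truth is planted on three isomers whose uniform fragment
#: templates are linearly independent.  With complete uniform b/y ladders
#: the six diacetyl isomers span only a rank-5 template space (fragment
#: m/z encode prefix acetyl counts, so one mixing direction is flat);
#: planting this support keeps the truth identifiable.  The
#: degree-of-acetylation summary is invariant to the flat direction.
_DI_W = {
    frozenset({12, 16}): 0.4,
    frozenset({8, 16}): 0.35,
    frozenset({5, 8}): 0.25,
}


@dataclass
class StudyFixture:
    chrom_sizes: dict[str, int]
    genes: list  # GeneRecord
    true_rpkm: pd.Series
    true_class: pd.Series
    chip_tags: dict[str, pd.DataFrame]  # protein -> raw tags
    control_tags: pd.DataFrame
    planted_islands: dict[str, pd.DataFrame]
    rnaseq_counts: pd.DataFrame
    rnaseq_library: int
    knockdown_log2fc: pd.Series  # planted Brd4-depletion response
    activator_bound_genes: list[str]
    acetyl_truth: dict[str, tuple]


def _h4_truth_vector(kind: str) -> dict[str, float]:
    """Expand a degree-of-acetylation 5-vector to the 16 configurations."""
    forms = h4_tail_proteoforms()
    per_class: dict[int, list[Proteoform]] = {}
    for p in forms:
        per_class.setdefault(p.n_acetyl, []).append(p)
    totals = ACETYL_TRUTH[kind]
    out = {}
    for k, members in per_class.items():
        for p in members:
            ac_sites = frozenset(m.site for m in p.modifications if m.kind == "ac")
            if k == 1:
                out[p.form_id] = totals[1] * _MONO_W[f"K{next(iter(ac_sites))}"]
            elif k == 2:
                out[p.form_id] = totals[2] * _DI_W.get(ac_sites, 0.0)
            else:
                out[p.form_id] = totals[k] / len(members)
    return out


def make_study_fixture(
    seed: int,
    chrom_size: int = 10_000_000,
    n_genes: int = 200,
    chip_background: float = 0.002,
) -> StudyFixture:
    """A 10-Mb, 200-gene, 5-protein miniature of the study design.

    Activator readers (Brd-like) are planted over the promoters and bodies
    of high-expression genes (8-fold) and medium genes (3-fold); repressor
    readers (HP1-like) over silent gene bodies (8-fold), medium bodies
    (3-fold) and a few intergenic blocks.  The ChIP background of
    2 tags/kb/strand corresponds to pooled-replicate depth; the control
    library has no planted enrichment.  The planted Brd4-knockdown table
    gives 75% of activator-bound genes at least a two-fold reduction and
    8% at least a two-fold increase, mirroring the reader-depletion design.
    """
    from .genome_annotation import GeneRecord

    rng = np.random.default_rng(seed)
    chrom_sizes = {"chr1": chrom_size}
    slot = chrom_size // n_genes
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        length = int(rng.integers(2_000, 8_000))
        margin = 3_000  # keep promoters/flanks inside the slot
        start = int(
            slot * i + rng.integers(margin, max(margin + 1, slot - length - margin))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                id=f"g{i:03d}",
                chrom="chr1",
                strand=strand,
                start=start,
                end=start + length,
            )
        )
    # expression truth: well-separated tertiles, 30/40/30
    idx = rng.permutation(n_genes)
    n_high = int(0.3 * n_genes)
    n_silent = int(0.3 * n_genes)
    true_class = pd.Series("medium", index=[g.id for g in genes])
    true_class.iloc[idx[:n_high]] = "high"
    true_class.iloc[idx[n_high : n_high + n_silent]] = "silent"
    level = {"high": 30.0, "medium": 3.0, "silent": 0.02}
    true_rpkm = pd.Series(
        [
            level[true_class[g.id]] * float(rng.lognormal(0.0, 0.25))
            for g in genes
        ],
        index=true_class.index,
    )

    def gene_islands(fold_by_class, include_promoter):
        isles = []
        for g in genes:
            fold = fold_by_class.get(true_class[g.id], 1.0)
            if fold <= 1.0:
                continue
            lo = g.start, g.end
            if include_promoter:
                if g.strand == "+":
                    lo = (g.start - 2000, g.end)
                else:
                    lo = (g.start, g.end + 2000)
            isles.append(PlantedIsland("chr1", max(0, lo[0]), lo[1], fold))
        return isles

    chip_tags = {}
    planted = {}
    for k, protein in enumerate(PROTEINS):
        if protein in ACTIVATORS:
            isles = gene_islands({"high": 8.0, "medium": 3.0}, include_promoter=True)
        else:
            isles = gene_islands({"silent": 8.0, "medium": 3.0}, include_promoter=False)
            # intergenic heterochromatin blocks between gene slots
            for b in range(5):
                start = int(slot * (7 * b + 3) + slot - 2_500)
                isles.append(PlantedIsland("chr1", start, start + 2_000, 8.0))
        isles.sort(key=lambda i: i.start)
        scen = GenomeScenario(
            chrom_sizes,
            islands=isles,
            background_rate=chip_background,
            seed=int(rng.integers(2**31)),
        )
        tags, truth = simulate_chip_reads(scen)
        chip_tags[protein] = tags
        planted[protein] = truth
    control_scen = GenomeScenario(
        chrom_sizes, background_rate=chip_background, seed=int(rng.integers(2**31))
    )
    control_tags, _ = simulate_chip_reads(control_scen)

    rnaseq_library = 5_000_000
    rnaseq_counts = simulate_rnaseq(
        genes, true_rpkm, rnaseq_library, seed=int(rng.integers(2**31))
    )

    # knockdown truth: 75% reduced / 8% increased among activator-bound
    # genes, with the quota applied within each expression class so any
    # binding-ranked subset mixing the classes carries the same fractions
    bound = [g.id for g in genes if true_class[g.id] in ("high", "medium")]
    fc = pd.Series(rng.uniform(-0.3, 0.3, n_genes), index=true_class.index)
    for cls in ("high", "medium"):
        stratum = [gid for gid in bound if true_class[gid] == cls]
        order = rng.permutation(len(stratum))
        n_red = round(0.75 * len(stratum))
        n_inc = round(0.08 * len(stratum))
        for j in order[:n_red]:
            fc[stratum[j]] = float(rng.uniform(-2.5, -1.0))
        for j in order[n_red : n_red + n_inc]:
            fc[stratum[j]] = float(rng.uniform(1.0, 2.0))

    return StudyFixture(
        chrom_sizes=chrom_sizes,
        genes=genes,
        true_rpkm=true_rpkm,
        true_class=true_class,
        chip_tags=chip_tags,
        control_tags=control_tags,
        planted_islands=planted,
        rnaseq_counts=rnaseq_counts,
        rnaseq_library=rnaseq_library,
        knockdown_log2fc=fc,
        activator_bound_genes=bound,
        acetyl_truth=ACETYL_TRUTH,
    )
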