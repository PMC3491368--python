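"""Quantification of modified histone peptides from centroided peak lists.

The measurement model: each proteoform elutes as a chromatographic peak;
its precursor is quantified by integrating an extracted ion chromatogram
(XIC).  Positional isomers with identical mass (e.g. the six diacetyl
arrangements of H4 K5/K8/K12/K16) co-elute and share one precursor, so
their joint MS/MS spectrum is a superposition of the members' fragment
patterns.  We recover the mixing proportions by non-negative least squares
against the members' theoretical fragment templates, apportion the shared
precursor area by those proportions, and normalize within each peptide
family to relative abundances summing to 100%.

Supported inputs: centroided mzML and MGF (via pyteomics) and a simple TSV
peak-list dialect used by the synthetic fixtures
(columns: scan, rt, level, precursor_mz, peaks as ``mz:intensity;...``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .ptm_chemistry import IsobaricGroup, Proteoform, precursor_mz

__all__ = [
    "Scan",
    "PeakList",
    "XIC",
    "DeconvolutionResult",
    "read_peaklist",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "extract_xic",
    "xic_apex",
    "integrate_peak",
    "pair_channels",
    "deconvolve_isobaric",
    "relative_abundance",
    "degree_of_acetylation",
    "quantify",
]


class QuantificationError(ValueError):
    pass


class IdentificationError(QuantificationError):
    """No theoretical fragment matched the observed spectrum."""


@dataclass
class Scan:
    rt: float  # seconds
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None  # MS2 only


@dataclass
class PeakList:
    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise QuantificationError("scans must be ordered by retention time")

    def ms1(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]


@dataclass
class XIC:
    target_mz: float
    ppm_tolerance: float
    rt: np.ndarray
    intensity: np.ndarray


@dataclass
class DeconvolutionResult:
    group: IsobaricGroup
    proportions: np.ndarray  # per member, sums to 1
    residual: float
    indeterminate: np.ndarray  # per member: no site-determining ion observed
    n_matched: int = 0


# --------------------------------------------------------------------------
# Peak-list I/O
# --------------------------------------------------------------------------


def read_peaklist_tsv(path) -> PeakList:
    df = pd.read_csv(path, sep="\t")
    scans = []
    for _, row in df.iterrows():
        pairs = str(row["peaks"])
        if pairs and pairs != "nan":
            arr = np.array(
                [p.split(":") for p in pairs.split(";") if p], dtype=float
            )
            mz, inten = arr[:, 0], arr[:, 1]
        else:
            mz = np.array([])
            inten = np.array([])
        prec = row.get("precursor_mz")
        scans.append(
            Scan(
                rt=float(row["rt"]),
                ms_level=int(row["level"]),
                mz=mz,
                intensity=inten,
                precursor_mz=None if pd.isna(prec) else float(prec),
            )
        )
    return PeakList(scans)


def write_peaklist_tsv(peaklist: PeakList, path) -> None:
    rows = []
    for i, s in enumerate(peaklist.scans):
        rows.append(
            {
                "scan": i + 1,
                "rt": s.rt,
                "level": s.ms_level,
                "precursor_mz": s.precursor_mz,
                "peaks": ";".join(
                    f"{m:.6f}:{v:.4f}" for m, v in zip(s.mz, s.intensity)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peaklist_mgf(path) -> PeakList:
    from pyteomics import mgf

    scans = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            rt = float(params.get("rtinseconds", 0.0))
            pep = params.get("pepmass")
            prec = float(pep[0]) if pep else None
            scans.append(
                Scan(
                    rt=rt,
                    ms_level=2,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                    precursor_mz=prec,
                )
            )
    scans.sort(key=lambda s: s.rt)
    return PeakList(scans)


def read_peaklist_mzml(path) -> PeakList:
    from pyteomics import mzml

    scans = []
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            level = int(spec.get("ms level", 1))
            rt = float(
                spec["scanList"]["scan"][0].get("scan start time", 0.0)
            )
            prec = None
            if level == 2:
                prec = float(
                    spec["precursorList"]["precursor"][0]["selectedIonList"][
                        "selectedIon"
                    ][0]["selected ion m/z"]
                )
            scans.append(
                Scan(
                    rt=rt * 60.0,  # mzML scan start time is in minutes
                    ms_level=level,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                    precursor_mz=prec,
                )
            )
    scans.sort(key=lambda s: s.rt)
    return PeakList(scans)


def read_peaklist(path) -> PeakList:
    p = str(path).lower()
    if p.endswith(".mzml"):
        return read_peaklist_mzml(path)
    if p.endswith(".mgf"):
        return read_peaklist_mgf(path)
    return read_peaklist_tsv(path)


# --------------------------------------------------------------------------
# XIC extraction and integration
# --------------------------------------------------------------------------


def extract_xic(peaklist: PeakList, target_mz: float, ppm_tolerance: float) -> XIC:
    """Summed MS1 intensity within ``ppm_tolerance`` of ``target_mz`` per scan."""
    if ppm_tolerance <= 0:
        raise QuantificationError("ppm tolerance must be positive")
    ms1 = peaklist.ms1()
    if not ms1:
        raise QuantificationError("peak list has no MS1 scans")
    tol = target_mz * ppm_tolerance * 1e-6
    rts = np.array([s.rt for s in ms1])
    intens = np.array(
        [
            float(s.intensity[np.abs(s.mz - target_mz) <= tol].sum())
            if s.mz.size
            else 0.0
            for s in ms1
        ]
    )
    return XIC(target_mz, ppm_tolerance, rts, intens)


def xic_apex(xic: XIC) -> float:
    """Retention time of the XIC apex (3-point moving average, tie -> earliest)."""
    y = xic.intensity
    if y.size >= 3:
        sm = np.convolve(y, np.ones(3) / 3, mode="same")
    else:
        sm = y
    return float(xic.rt[int(np.argmax(sm))])


def integrate_peak(xic: XIC, rt_window: tuple[float, float]) -> float:
    """Trapezoidal area of the XIC over ``rt_window`` (intensity x seconds)."""
    lo, hi = rt_window
    mask = (xic.rt >= lo) & (xic.rt <= hi)
    if mask.sum() < 2:
        warnings.warn("RT window contains fewer than two XIC points; area = 0")
        return 0.0
    return float(np.trapezoid(xic.intensity[mask], xic.rt[mask]))


def pair_channels(d0_area: float, d5_area: float) -> tuple[float, str]:
    """d0/d5 area ratio with explicit sentinels for empty channels."""
    if d0_area < 0 or d5_area < 0:
        raise QuantificationError("areas must be non-negative")
    if d0_area == 0 and d5_area == 0:
        return (math.nan, "missing")
    if d5_area == 0:
        return (math.inf, "d5_zero")
    return (d0_area / d5_area, "ok")


# --------------------------------------------------------------------------
# Superposition deconvolution
# --------------------------------------------------------------------------


def _template_matrix(
    group: IsobaricGroup, match_tolerance_ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row m/z axis (clustered theoretical ions) and member template matrix.

    Templates are uniform over each member's b/y ions, column-normalized.
    Rows theoretical for one member but absent from the observation then
    penalize that member in the least-squares fit.
    """
    all_mz = np.unique(np.concatenate([f.mz_values() for f in group.fragments]))
    rows: list[float] = []
    for v in all_mz:
        if rows and (v - rows[-1]) / rows[-1] * 1e6 <= match_tolerance_ppm:
            continue
        rows.append(float(v))
    row_mz = np.array(rows)
    a = np.zeros((row_mz.size, len(group.members)))
    for j, frag in enumerate(group.fragments):
        for v in frag.mz_values():
            i = int(np.argmin(np.abs(row_mz - v)))
            if abs(row_mz[i] - v) / v * 1e6 <= match_tolerance_ppm:
                a[i, j] += 1.0
    col_sums = a.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    return row_mz, a / col_sums


def deconvolve_isobaric(
    ms2_mz: np.ndarray,
    ms2_intensity: np.ndarray,
    group: IsobaricGroup,
    match_tolerance_ppm: float = 20.0,
) -> DeconvolutionResult:
    """Resolve a mixed MS/MS spectrum of co-eluting isobaric proteoforms.

    Solves min ||A x - o||, x >= 0, where the columns of A are the members'
    normalized theoretical fragment templates and o is the observed
    intensity matched to the template m/z rows (unmatched rows contribute
    zeros).  Proportions are x renormalized to sum to one; members with no
    site-determining ion in the observation are flagged indeterminate.
    """
    if not group.members:
        raise QuantificationError("empty isobaric group")
    ms2_mz = np.asarray(ms2_mz, dtype=float)
    ms2_intensity = np.asarray(ms2_intensity, dtype=float)
    row_mz, a = _template_matrix(group, match_tolerance_ppm)
    # each observed peak contributes to its nearest template row only
    o = np.zeros(row_mz.size)
    if ms2_mz.size:
        nearest = np.clip(
            np.searchsorted(row_mz, ms2_mz), 1, row_mz.size - 1
        )
        left = nearest - 1
        pick = np.where(
            np.abs(row_mz[left] - ms2_mz) <= np.abs(row_mz[nearest] - ms2_mz),
            left,
            nearest,
        )
        ok = np.abs(row_mz[pick] - ms2_mz) / ms2_mz * 1e6 <= match_tolerance_ppm
        np.add.at(o, pick[ok], ms2_intensity[ok])
    n_matched = int(np.count_nonzero(o))
    if n_matched == 0:
        raise IdentificationError("no theoretical fragment matched the spectrum")
    if len(group.members) == 1:
        return DeconvolutionResult(
            group, np.array([1.0]), 0.0, np.array([False]), n_matched
        )
    x, rnorm = nnls(a, o)
    total = x.sum()
    if total == 0:
        raise IdentificationError("all mixing coefficients are zero")
    proportions = x / total
    indet = np.zeros(len(group.members), dtype=bool)
    for j, det_mz in enumerate(group.site_determining):
        if det_mz.size == 0:
            indet[j] = True
            continue
        seen = any(
            np.any(np.abs(ms2_mz - v) <= v * match_tolerance_ppm * 1e-6)
            for v in det_mz
        )
        indet[j] = not seen
    return DeconvolutionResult(group, proportions, float(rnorm), indet, n_matched)


# --------------------------------------------------------------------------
# Relative abundance
# --------------------------------------------------------------------------


def relative_abundance(
    group_areas: Sequence[tuple[IsobaricGroup, float]],
    deconvolutions: Sequence[DeconvolutionResult | None],
    sample: str = "sample",
    replicate: str = "r1",
    family: str | None = None,
) -> pd.DataFrame:
    """Split shared precursor areas by mixing proportions, normalize to 100%.

    ``deconvolutions[i]`` may be None for singleton groups.  Families with
    zero total area are dropped with a warning.
    """
    rows = []
    for (group, area), dec in zip(group_areas, deconvolutions):
        if len(group.members) == 1:
            props = np.array([1.0])
        elif dec is None:
            raise QuantificationError("multi-member group requires a deconvolution")
        else:
            props = dec.proportions
        for member, p in zip(group.members, props):
            rows.append(
                {
                    "family": family
                    or f"{member.protein}_{member.residue_span[0]}-{member.residue_span[1]}",
                    "form": member.form_id,
                    "n_acetyl": member.n_acetyl,
                    "area": area * float(p),
                    "sample": sample,
                    "replicate": replicate,
                }
            )
    df = pd.DataFrame(rows)
    total = df["area"].sum()
    if total == 0:
        warnings.warn("family total area is zero; family dropped")
        return df.iloc[0:0].assign(abundance_pct=[])
    df["abundance_pct"] = df["area"] / total * 100.0
    return df.drop(columns="area")


def degree_of_acetylation(h4_family_table: pd.DataFrame) -> pd.Series:
    """Un/mono/di/tri/tetra-acetyl totals of the H4 4-17 family (sum = 100).

    Configurations absent from the table count as zero.
    """
    n_config = h4_family_table["form"].nunique()
    if n_config < 16:
        warnings.warn(
            f"only {n_config}/16 acetyl configurations present; missing = 0"
        )
    labels = ["un", "mono", "di", "tri", "tetra"]
    sums = h4_family_table.groupby("n_acetyl")["abundance_pct"].sum()
    return pd.Series(
        [float(sums.get(k, 0.0)) for k in range(5)], index=labels, name="pct"
    )


# --------------------------------------------------------------------------
# End-to-end quantification of one run
# --------------------------------------------------------------------------


def quantify(
    peaklist: PeakList,
    groups: Sequence[IsobaricGroup],
    charge: int = 2,
    precursor_ppm: float = 10.0,
    fragment_ppm: float = 20.0,
    rt_halfwidth: float = 30.0,
    sample: str = "sample",
    replicate: str = "r1",
) -> pd.DataFrame:
    """XIC -> apex window integration -> MS2 deconvolution -> AbundanceTable.

    For multi-member groups, every matching MS2 scan inside the RT peak
    window contributes; proportions are averaged weighted by scan total
    intensity (nearest-in-RT scan if none falls inside the window).
    """
    group_areas: list[tuple[IsobaricGroup, float]] = []
    decs: list[DeconvolutionResult | None] = []
    ms2 = peaklist.ms2()
    for group in groups:
        mz = precursor_mz(group.mass, charge)
        xic = extract_xic(peaklist, mz, precursor_ppm)
        apex = xic_apex(xic)
        area = integrate_peak(xic, (apex - rt_halfwidth, apex + rt_halfwidth))
        group_areas.append((group, area))
        if len(group.members) == 1:
            decs.append(None)
            continue
        matching = [
            s
            for s in ms2
            if s.precursor_mz is not None
            and abs(s.precursor_mz - mz) / mz * 1e6 <= precursor_ppm
        ]
        if not matching:
            raise IdentificationError(
                f"no MS2 scan matches group precursor m/z {mz:.4f}"
            )
        in_window = [s for s in matching if abs(s.rt - apex) <= rt_halfwidth]
        if not in_window:
            in_window = [min(matching, key=lambda s: abs(s.rt - apex))]
        props = np.zeros(len(group.members))
        weight = 0.0
        result = None
        for s in in_window:
            result = deconvolve_isobaric(s.mz, s.intensity, group, fragment_ppm)
            w = float(s.intensity.sum())
            props += w * result.proportions
            weight += w
        props = props / weight if weight > 0 else result.proportions
        decs.append(
            DeconvolutionResult(
                group, props, result.residual, result.indeterminate, result.n_matched
            )
        )
    return relative_abundance(
        group_areas, decs, sample=sample, replicate=replicate
    )
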