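"""Propionylation/trypsin chemistry of histone tails.

Bottom-up histone PTM analysis derivatizes free and monomethyl lysine
epsilon-amines (and, after digestion, the new peptide N-termini) with
propionic anhydride.  Propionylated lysines are no longer tryptic cleavage
sites, so trypsin cuts C-terminal to arginine only and histone tails yield
a small, reproducible set of peptides (e.g. the H4 4-17 tail peptide
GKGGKGLGKGGAKR carrying K5/K8/K12/K16).  The propionyl group comes in a
light (d0) and a heavy (d5, +5 deuterium) isotopic channel so that two
samples can be mixed and compared in one LC-MS/MS run.

This module enumerates candidate proteoforms (site-resolved modification
assignments) for such peptides, computes their monoisotopic masses and b/y
fragment ladders, and groups proteoforms that are isobaric -- identical in
mass, distinguishable only through site-determining fragment ions.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Monoisotopic constants (Da).  Validated in the test suite against an
# independent composition-based oracle (pyteomics).
# --------------------------------------------------------------------------

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863

#: Residue (amino-acid minus water) monoisotopic masses.
AA_MONO: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Modification mass deltas.  d5-propionyl replaces five H with five D:
#: 5 x (2.01410178 - 1.00782503) = 5.03138 Da heavier than d0.
MOD_DELTAS: dict[str, float] = {
    "unmodified": 0.0,
    "me1": 14.01565,
    "me2": 28.03130,
    "me3": 42.04695,
    "ac": 42.01057,
    "propionyl-d0": 56.02621,
    "propionyl-d5": 61.05759,
}

#: Lysine states whose epsilon-amine stays free and is therefore
#: derivatized with a propionyl group; me2/me3/ac amines are blocked.
PROPIONYLATABLE_KINDS = frozenset({"unmodified", "me1"})

MOD_KINDS = frozenset(MOD_DELTAS)

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class ChemistryError(ValueError):
    """Invalid sequence, site or modification assignment."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModificationSpec:
    """One site-level modification (1-based protein coordinates)."""

    kind: str
    site: int

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise ChemistryError(f"unknown modification kind {self.kind!r}")

    @property
    def mass_delta(self) -> float:
        return MOD_DELTAS[self.kind]


@dataclass(frozen=True)
class Proteoform:
    """A peptide with a full site-level modification assignment.

    ``modifications`` holds exactly one :class:`ModificationSpec` per lysine
    in the peptide, ordered by site.  ``label_channel`` selects the d0 or d5
    propionyl chemistry; the propionyl groups themselves are implied by the
    placement rules (free/me1 lysines and the peptide N-terminus) rather
    than listed explicitly.
    """

    protein: str
    peptide_sequence: str
    residue_span: tuple[int, int]  # 1-based inclusive on the protein
    modifications: tuple[ModificationSpec, ...]
    label_channel: str = "d0"
    n_terminal_propionyl: bool = True

    def __post_init__(self) -> None:
        start, end = self.residue_span
        if end - start + 1 != len(self.peptide_sequence):
            raise ChemistryError("residue_span length != sequence length")
        if self.label_channel not in ("d0", "d5"):
            raise ChemistryError(f"bad label channel {self.label_channel!r}")
        k_sites = {
            start + i for i, aa in enumerate(self.peptide_sequence) if aa == "K"
        }
        mod_sites = [m.site for m in self.modifications]
        if sorted(mod_sites) != sorted(k_sites) or len(set(mod_sites)) != len(
            mod_sites
        ):
            raise ChemistryError(
                "modifications must cover every lysine exactly once "
                f"(lysines {sorted(k_sites)}, got {sorted(mod_sites)})"
            )

    @property
    def propionyl_kind(self) -> str:
        return "propionyl-d0" if self.label_channel == "d0" else "propionyl-d5"

    @property
    def n_propionyl(self) -> int:
        """Number of propionyl groups (N-terminus + free/me1 lysines)."""
        n = int(self.n_terminal_propionyl)
        n += sum(1 for m in self.modifications if m.kind in PROPIONYLATABLE_KINDS)
        return n

    @property
    def form_id(self) -> str:
        """Human-readable site string, e.g. ``K5ac-K8prop-K12ac-K16prop``."""
        parts = []
        for m in sorted(self.modifications, key=lambda m: m.site):
            tag = {"unmodified": "prop"}.get(m.kind, m.kind)
            if m.kind == "me1":
                tag = "me1prop"
            parts.append(f"K{m.site}{tag}")
        return "-".join(parts) if parts else "unmod"

    @property
    def n_acetyl(self) -> int:
        return sum(1 for m in self.modifications if m.kind == "ac")

    def with_channel(self, channel: str) -> "Proteoform":
        return Proteoform(
            self.protein,
            self.peptide_sequence,
            self.residue_span,
            self.modifications,
            label_channel=channel,
            n_terminal_propionyl=self.n_terminal_propionyl,
        )


@dataclass(frozen=True)
class FragmentPattern:
    """b/y fragment ladder of one proteoform: (series, ordinal, charge, m/z)."""

    proteoform: Proteoform
    entries: tuple[tuple[str, int, int, float], ...]

    def mz_values(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries])


@dataclass
class IsobaricGroup:
    """Proteoforms indistinguishable by precursor mass.

    ``site_determining`` lists, per member, the fragment m/z values unique
    to it within the group -- the ions that carry positional information.
    """

    members: list[Proteoform]
    mass: float
    fragments: list[FragmentPattern] = field(default_factory=list)
    site_determining: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def digest_protein(
    protein_sequence: str, max_missed_cleavages: int = 0
) -> list[tuple[int, int]]:
    """Tryptic digest of a propionylated protein: cleave after R only.

    Protein-level propionylation blocks every lysine, so arginine is the
    only cleavage site.  Returns 1-based inclusive spans; with
    ``max_missed_cleavages`` > 0, spans joining up to that many adjacent
    fully-cleaved peptides are appended.
    """
    seq = protein_sequence.upper()
    if not _AA_RE.match(seq):
        raise ChemistryError("sequence contains non-amino-acid characters")
    cut_after = [i + 1 for i, aa in enumerate(seq) if aa == "R"]
    bounds = [0] + cut_after
    if bounds[-1] != len(seq):
        bounds.append(len(seq))
    base = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    spans = list(base)
    for miss in range(1, max_missed_cleavages + 1):
        for i in range(len(base) - miss):
            spans.append((base[i][0], base[i + miss][1]))
    return sorted(set(spans))


def enumerate_proteoforms(
    protein: str,
    protein_sequence: str,
    span: tuple[int, int],
    allowed_mods_per_site: Mapping[int, Sequence[str]],
    label_channel: str = "d0",
) -> list[Proteoform]:
    """All proteoforms of a peptide given per-lysine allowed modification sets.

    ``allowed_mods_per_site`` maps 1-based protein residue indices of
    lysines to the modification kinds allowed there.  Every lysine in the
    span must be covered; the output size is the product of the per-site
    counts.
    """
    start, end = span
    peptide = protein_sequence[start - 1 : end]
    k_sites = [start + i for i, aa in enumerate(peptide) if aa == "K"]
    for site in allowed_mods_per_site:
        if site not in k_sites:
            raise ChemistryError(f"site {site} is not a lysine inside span {span}")
    for site in k_sites:
        if not allowed_mods_per_site.get(site):
            raise ChemistryError(f"no allowed modifications for lysine {site}")
    choices = [
        [ModificationSpec(kind, site) for kind in allowed_mods_per_site[site]]
        for site in k_sites
    ]
    forms = []
    for combo in itertools.product(*choices):
        forms.append(
            Proteoform(
                protein=protein,
                peptide_sequence=peptide,
                residue_span=span,
                modifications=tuple(combo),
                label_channel=label_channel,
            )
        )
    return forms


def monoisotopic_mass(proteoform: Proteoform) -> float:
    """Neutral monoisotopic mass: residues + water + PTM and label deltas."""
    mass = WATER_MASS + sum(AA_MONO[aa] for aa in proteoform.peptide_sequence)
    mass += sum(m.mass_delta for m in proteoform.modifications)
    mass += proteoform.n_propionyl * MOD_DELTAS[proteoform.propionyl_kind]
    return mass


def precursor_mz(mass: float, charge: int) -> float:
    if charge < 1:
        raise ChemistryError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


def fragment_ions(
    proteoform: Proteoform, max_fragment_charge: int = 1
) -> FragmentPattern:
    """b- and y-ion ladders with modification deltas apportioned by site.

    The N-terminal propionyl travels with every b ion and with the full-
    length y ion only; lysine modifications (and their propionyl labels)
    travel with whichever fragments contain the residue.
    """
    seq = proteoform.peptide_sequence
    n = len(seq)
    start = proteoform.residue_span[0]
    prop = MOD_DELTAS[proteoform.propionyl_kind]
    # per-residue added mass (PTM + propionyl label where placed)
    extra = np.zeros(n)
    for m in proteoform.modifications:
        idx = m.site - start
        extra[idx] += m.mass_delta
        if m.kind in PROPIONYLATABLE_KINDS:
            extra[idx] += prop
    residue = np.array([AA_MONO[aa] for aa in seq]) + extra
    nterm = prop if proteoform.n_terminal_propionyl else 0.0
    prefix = np.cumsum(residue)
    entries = []
    for z in range(1, max_fragment_charge + 1):
        for i in range(1, n):
            b = prefix[i - 1] + nterm
            entries.append(("b", i, z, (b + z * PROTON_MASS) / z))
        for i in range(1, n):
            y = prefix[-1] - prefix[n - i - 1] + WATER_MASS
            entries.append(("y", i, z, (y + z * PROTON_MASS) / z))
    return FragmentPattern(proteoform, tuple(entries))


def isobaric_groups(
    proteoforms: Sequence[Proteoform],
    mass_tolerance_ppm: float = 10.0,
    fragment_tolerance_ppm: float = 20.0,
) -> list[IsobaricGroup]:
    """Partition proteoforms of one peptide into isobaric mass groups.

    Proteoforms are clustered greedily on sorted mass with single linkage at
    ``mass_tolerance_ppm``; for each group member the site-determining
    fragment m/z values (those not shared, within ``fragment_tolerance_ppm``,
    with any other member) are recorded.
    """
    if not proteoforms:
        return []
    seqs = {p.peptide_sequence for p in proteoforms}
    if len(seqs) > 1:
        raise ChemistryError("isobaric grouping requires a single peptide sequence")
    masses = np.array([monoisotopic_mass(p) for p in proteoforms])
    order = np.argsort(masses)
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        prev = groups[-1][-1]
        if (masses[idx] - masses[prev]) / masses[prev] * 1e6 <= mass_tolerance_ppm:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    out = []
    for g in groups:
        members = [proteoforms[i] for i in g]
        frags = [fragment_ions(p) for p in members]
        mzs = [f.mz_values() for f in frags]
        site_det = []
        for i, mz_i in enumerate(mzs):
            others = (
                np.concatenate([mzs[j] for j in range(len(mzs)) if j != i])
                if len(mzs) > 1
                else np.array([])
            )
            if others.size:
                shared = np.array(
                    [
                        np.any(np.abs(others - v) / v * 1e6 <= fragment_tolerance_ppm)
                        for v in mz_i
                    ]
                )
                site_det.append(np.unique(mz_i[~shared]))
            else:
                site_det.append(np.unique(mz_i))
        out.append(
            IsobaricGroup(
                members=members,
                mass=float(masses[g].mean()),
                fragments=frags,
                site_determining=site_det,
            )
        )
    out.sort(key=lambda grp: grp.mass)
    return out


# --------------------------------------------------------------------------
# Reference sequences and catalog serialization
# --------------------------------------------------------------------------


def load_reference_sequences() -> dict[str, str]:
    """Built-in mature human histone H3.1 and H4 sequences."""
    from Bio import SeqIO

    ref = resources.files("readerscope.data") / "histones.fasta"
    with resources.as_file(ref) as path:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def h4_tail_proteoforms(
    acetyl_only: bool = True, label_channel: str = "d0"
) -> list[Proteoform]:
    """The 16 acetyl configurations of the H4 4-17 peptide (K5/K8/K12/K16)."""
    h4 = load_reference_sequences()["H4"]
    allowed = ["unmodified", "ac"] if acetyl_only else [
        "unmodified",
        "me1",
        "me2",
        "me3",
        "ac",
    ]
    sites = {5: allowed, 8: allowed, 12: allowed, 16: allowed}
    return enumerate_proteoforms("H4", h4, (4, 17), sites, label_channel)


def catalog_frame(proteoforms: Iterable[Proteoform], charges=(1, 2)) -> "pd.DataFrame":
    """Proteoform catalog as a table (TSV-ready)."""
    import pandas as pd

    rows = []
    for p in proteoforms:
        mass = monoisotopic_mass(p)
        row = {
            "protein": p.protein,
            "span": f"{p.residue_span[0]}-{p.residue_span[1]}",
            "sequence": p.peptide_sequence,
            "form": p.form_id,
            "channel": p.label_channel,
            "neutral_mass": round(mass, 5),
        }
        for z in charges:
            row[f"mz_z{z}"] = round(precursor_mz(mass, z), 5)
        rows.append(row)
    return pd.DataFrame(rows)
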