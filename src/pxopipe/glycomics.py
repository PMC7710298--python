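"""Permethylated N-glycan annotation, subtype classification and profiling.

MALDI-TOF peak lists of permethylated N-glycans are annotated with
monosaccharide compositions written as ``H{h}N{n}F{f}S{s}`` (hexose,
N-acetylhexosamine, deoxyhexose/fucose, N-acetylneuraminic acid; zero counts
omitted).  Compositions are classified into the four canonical N-glycan
subtypes (high-mannose, pauci-mannose, hybrid, complex) plus derived traits
(degree of sialylation = S, fucosylation = F), and per-sample profiles are
compared across matched in vivo (PDX) / organoid (PXO) samples.

Masses are monoisotopic and derived from atomic formulas of the fully
methylated residues, not from hard-coded literature increments, so the mass
table can be audited element by element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GlycanComposition",
    "GlycanProfile",
    "SubtypeCall",
    "parse_composition",
    "permethylated_mass",
    "annotate_peaks",
    "classify_subtype",
    "relative_abundance",
    "cross_sample_analysis",
    "enumerate_compositions",
]

# Monoisotopic atomic masses (CODATA/AME; u).
_ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
}
_ELECTRON_MASS = 0.00054857990


def _formula_mass(formula: Mapping[str, int]) -> float:
    return float(sum(_ELEMENT_MASS[el] * n for el, n in formula.items()))


# Residue formulas AFTER full methylation, as chain increments (monosaccharide
# minus water, every free OH/NH hydrogen replaced by CH3 in the polymer
# context).  These reproduce the standard permethylated increments:
# Hex 204.0998, HexNAc 245.1263, dHex 174.0892, NeuAc 361.1737.
_PERMETHYL_RESIDUE_FORMULA = {
    "H": {"C": 9, "H": 16, "O": 5},   # hexose
    "N": {"C": 11, "H": 19, "N": 1, "O": 5},  # HexNAc
    "F": {"C": 8, "H": 14, "O": 4},   # deoxyhexose (fucose)
    "S": {"C": 16, "H": 27, "N": 1, "O": 8},  # NeuAc
}
# Chain termini of the free-reducing-end permethylated glycan: one O-methyl
# at the reducing end plus the methylated non-reducing terminus, net C2H6O.
_TERMINAL_FORMULA = {"C": 2, "H": 6, "O": 1}

PERMETHYL_RESIDUE_MASS = {
    k: _formula_mass(v) for k, v in _PERMETHYL_RESIDUE_FORMULA.items()
}
TERMINAL_MASS = _formula_mass(_TERMINAL_FORMULA)

# Singly charged adducts; m/z = M + adduct mass (electron removed).
ADDUCT_MASS = {
    "Na": _ELEMENT_MASS["Na"] - _ELECTRON_MASS,
    "H": _ELEMENT_MASS["H"] - _ELECTRON_MASS,
}

_COMPOSITION_RE = re.compile(
    r"^(?:H(?P<H>\d+))?(?:N(?P<N>\d+))?(?:F(?P<F>\d+))?(?:S(?P<S>\d+))?$"
)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide composition of an N-glycan.

    H = hexose, N = N-acetylhexosamine (GlcNAc at composition level),
    F = deoxyhexose (fucose), S = N-acetylneuraminic acid.
    """

    H: int = 0
    N: int = 0
    F: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for letter in "HNFS":
            v = getattr(self, letter)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{letter} count must be a non-negative integer, got {v!r}")

    @property
    def total_residues(self) -> int:
        return self.H + self.N + self.F + self.S

    def canonical(self) -> str:
        """Canonical string, zero counts omitted, HNFS order."""
        parts = [f"{letter}{getattr(self, letter)}"
                 for letter in "HNFS" if getattr(self, letter) > 0]
        if not parts:
            return "empty"
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def parse_composition(text: str) -> GlycanComposition:
    """Parse a canonical composition string such as ``"H5N2"`` or ``"H3N4F1"``.

    Letters may be omitted (count 0) but must appear in H,N,F,S order.
    Raises ``ValueError`` for anything else (e.g. ``"X9"``).
    """
    s = text.strip()
    if not s:
        raise ValueError("empty composition string")
    m = _COMPOSITION_RE.match(s)
    if m is None or all(g is None for g in m.groups()):
        raise ValueError(f"malformed glycan composition: {text!r}")
    counts = {k: int(v) if v is not None else 0 for k, v in m.groupdict().items()}
    return GlycanComposition(**counts)


def permethylated_mass(comp: GlycanComposition, adduct: str = "Na") -> float:
    """m/z of the singly charged permethylated glycan with the given adduct.

    Sum of permethylated residue increments plus the chain-terminal group,
    plus the adduct mass.  The sodiated ion [M+Na]+ is the MALDI default.
    """
    if adduct not in ADDUCT_MASS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_MASS)}")
    mass = TERMINAL_MASS + ADDUCT_MASS[adduct]
    for letter in "HNFS":
        mass += getattr(comp, letter) * PERMETHYL_RESIDUE_MASS[letter]
    return mass


def classify_subtype(comp: GlycanComposition) -> "SubtypeCall":
    """Assign one of the four N-glycan subtypes from composition alone.

    Rule table (composition-level heuristic; hybrid vs complex is not fully
    resolvable without structure, borderline N=3 calls are flagged ambiguous):

    * high-mannose: N=2 with 5-9 hexoses, no fucose or sialic acid;
    * pauci-mannose: N=2 with at most 3 hexoses (any F, S), or N=2, H=4
      with core fucose;
    * hybrid: N=3 with at least 5 hexoses (mannose arm plus one antenna);
    * complex: everything else (antennae initiated by GlcNAc).
    """
    if comp.N < 2:
        raise ValueError(
            f"not a valid N-glycan composition (needs chitobiose core, N>=2): {comp.canonical()}"
        )
    ambiguous = False
    if comp.N == 2 and 5 <= comp.H <= 9 and comp.F == 0 and comp.S == 0:
        subtype = "high-mannose"
    elif comp.N == 2 and (comp.H <= 3 or (comp.H == 4 and comp.F >= 1)):
        subtype = "pauci-mannose"
    elif comp.N == 3 and comp.H >= 5:
        subtype = "hybrid"
        ambiguous = True
    else:
        subtype = "complex"
        ambiguous = comp.N == 3
    return SubtypeCall(
        composition=comp,
        subtype=subtype,
        sialylation=comp.S,
        fucosylation=comp.F,
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class SubtypeCall:
    composition: GlycanComposition
    subtype: str  # high-mannose | pauci-mannose | hybrid | complex
    sialylation: int
    fucosylation: int
    ambiguous: bool = False


@dataclass
class GlycanProfile:
    """Per-sample map composition -> intensity, with provenance.

    ``source`` distinguishes in vivo xenograft ("PDX") from organoid ("PXO")
    samples in the cross-sample analysis.
    """

    sample_id: str
    source: str  # "PDX" | "PXO"
    intensities: dict[GlycanComposition, float] = field(default_factory=dict)
    unassigned: list[tuple[float, float]] = field(default_factory=list)

    def compositions(self) -> set[GlycanComposition]:
        return {c for c, v in self.intensities.items() if v > 0}

    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))


def relative_abundance(profile: GlycanProfile) -> GlycanProfile:
    """Return a copy with intensities normalized to sum to one."""
    total = profile.total_intensity()
    if total <= 0:
        raise ValueError(f"profile {profile.sample_id} has zero total intensity")
    return GlycanProfile(
        sample_id=profile.sample_id,
        source=profile.source,
        intensities={c: v / total for c, v in profile.intensities.items()},
        unassigned=list(profile.unassigned),
    )


def enumerate_compositions(
    max_h: int = 12,
    max_n: int = 10,
    max_f: int = 5,
    max_s: int = 6,
    mz_range: tuple[float, float] = (500.0, 6000.0),
    adduct: str = "Na",
) -> list[tuple[GlycanComposition, float]]:
    """All candidate N-glycan compositions (N>=2) whose permethylated m/z lies
    in ``mz_range``, with their masses, sorted by mass."""
    out: list[tuple[GlycanComposition, float]] = []
    lo, hi = mz_range
    for n in range(2, max_n + 1):
        for h in range(0, max_h + 1):
            for f in range(0, max_f + 1):
                for s in range(0, max_s + 1):
                    comp = GlycanComposition(H=h, N=n, F=f, S=s)
                    mz = permethylated_mass(comp, adduct=adduct)
                    if lo <= mz <= hi:
                        out.append((comp, mz))
    out.sort(key=lambda t: t[1])
    return out


def annotate_peaks(
    peaks: Sequence[tuple[float, float]],
    sample_id: str = "sample",
    source: str = "PXO",
    tolerance_ppm: float = 20.0,
    mz_range: tuple[float, float] = (500.0, 6000.0),
    adduct: str = "Na",
    candidates: Sequence[tuple[GlycanComposition, float]] | None = None,
) -> GlycanProfile:
    """Assign each picked peak the composition minimizing |ppm error|.

    Peaks outside ``mz_range`` are dropped (the instrument window); peaks with
    no candidate within ``tolerance_ppm`` are reported as unassigned.  Exact
    ppm ties go to the composition with fewer total residues.  Multiple peaks
    mapping to the same composition have their intensities summed.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if candidates is None:
        candidates = enumerate_compositions(mz_range=mz_range, adduct=adduct)
    masses = np.array([m for _, m in candidates])
    comps = [c for c, _ in candidates]

    profile = GlycanProfile(sample_id=sample_id, source=source)
    lo, hi = mz_range
    for mz, intensity in peaks:
        if not (lo <= mz <= hi):
            continue
        ppm = (masses - mz) / mz * 1e6
        abs_ppm = np.abs(ppm)
        within = abs_ppm <= tolerance_ppm
        if not within.any():
            profile.unassigned.append((float(mz), float(intensity)))
            continue
        best_err = abs_ppm[within].min()
        # exact-tie rule: among candidates at the minimal |ppm|, fewest residues
        tied = np.flatnonzero(within & (abs_ppm <= best_err + 1e-12))
        best = min(tied, key=lambda i: (comps[i].total_residues, comps[i]))
        comp = comps[best]
        profile.intensities[comp] = profile.intensities.get(comp, 0.0) + float(intensity)
    return profile


@dataclass
class OverlapReport:
    """Cross-sample census of glycan occurrence and abundance."""

    union: set[GlycanComposition]
    core: set[GlycanComposition]              # present in every sample
    categories: dict[GlycanComposition, str]  # paired | discordant | PDX-only | PXO-only
    occurrence: dict[GlycanComposition, int]
    core_abundance: dict[str, float]          # per sample: summed rel. abundance of core set
    subtype_abundance: dict[str, dict[str, float]]  # per sample: subtype -> rel. abundance
    n_union: int = 0
    n_core: int = 0

    def __post_init__(self) -> None:
        self.n_union = len(self.union)
        self.n_core = len(self.core)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cat in self.categories.values():
            counts[cat] = counts.get(cat, 0) + 1
        return counts


def cross_sample_analysis(
    profiles: Iterable[GlycanProfile],
    pairing: Mapping[str, str],
) -> OverlapReport:
    """Census of glycans across matched PDX/PXO samples.

    ``pairing`` maps PDX sample ids to their matched PXO sample ids.  Each
    glycan in the union is categorized: *paired* if present in both members of
    at least one matched pair; *discordant* if present in both sources but
    never within a matched pair; otherwise *PDX-only* / *PXO-only*.
    """
    profiles = list(profiles)
    by_id = {p.sample_id: p for p in profiles}
    for a, b in pairing.items():
        for sid in (a, b):
            if sid not in by_id:
                raise ValueError(f"pairing references unknown sample {sid!r}")
    sources = {p.source for p in profiles}
    if not {"PDX", "PXO"} <= sources:
        raise ValueError("need at least one profile per source (PDX and PXO)")

    presence = {p.sample_id: p.compositions() for p in profiles}
    union: set[GlycanComposition] = set().union(*presence.values())
    core = set.intersection(*presence.values()) if presence else set()

    pdx_ids = [p.sample_id for p in profiles if p.source == "PDX"]
    pxo_ids = [p.sample_id for p in profiles if p.source == "PXO"]

    categories: dict[GlycanComposition, str] = {}
    occurrence: dict[GlycanComposition, int] = {}
    for g in union:
        occurrence[g] = sum(1 for s in presence.values() if g in s)
        in_pdx = any(g in presence[i] for i in pdx_ids)
        in_pxo = any(g in presence[i] for i in pxo_ids)
        if in_pdx and in_pxo:
            paired = any(
                g in presence[a] and g in presence[b] for a, b in pairing.items()
            )
            categories[g] = "paired" if paired else "discordant"
        elif in_pdx:
            categories[g] = "PDX-only"
        else:
            categories[g] = "PXO-only"

    core_abundance: dict[str, float] = {}
    subtype_abundance: dict[str, dict[str, float]] = {}
    for p in profiles:
        rel = relative_abundance(p)
        core_abundance[p.sample_id] = float(
            sum(v for c, v in rel.intensities.items() if c in core)
        )
        by_subtype: dict[str, float] = {}
        for c, v in rel.intensities.items():
            st = classify_subtype(c).subtype
            by_subtype[st] = by_subtype.get(st, 0.0) + v
        subtype_abundance[p.sample_id] = by_subtype

    return OverlapReport(
        union=union,
        core=core,
        categories=categories,
        occurrence=occurrence,
        core_abundance=core_abundance,
        subtype_abundance=subtype_abundance,
    )
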