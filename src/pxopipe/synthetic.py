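"""Synthetic study data with planted ground truth.

Every input kind the analysis modules consume can be generated here with
known parameters, so each downstream stage has a test surface with a
recoverable truth: organoid viability plates around planted logistic curves,
PDX caliper series with exponential growth and arm-specific effect sizes,
N-glycan profiles with a planted core set shared by all samples, EV protein
matrices with planted enriched markers, marker blot tables with planted
cohort shifts, and pre-made normalized-AUC cohorts with a planted
sensitivity threshold.

All randomness flows through one ``numpy`` Generator seeded from
``SimulationConfig.seed``; a fixed config reproduces identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseResponsePlate
from .glycomics import (
    GlycanComposition,
    GlycanProfile,
    classify_subtype,
    parse_composition,
)

__all__ = [
    "SimulationConfig",
    "EVTables",
    "AUCCohort",
    "default_core_glycans",
    "gen_dose_response",
    "gen_pdx_growth",
    "gen_glycan_profiles",
    "gen_ev_tables",
    "gen_auc_cohort",
]

_DEFAULT_LOGISTIC_PARAMS: dict[str, dict[str, float]] = {
    # bottom/top in viability fraction, xmid log10 molar, slope per log10
    "gemcitabine": {"bottom": 0.10, "top": 1.0, "xmid": -6.5, "slope": 1.2},
    "paclitaxel": {"bottom": 0.05, "top": 1.0, "xmid": -7.0, "slope": 1.0},
    "oxaliplatin": {"bottom": 0.40, "top": 1.0, "xmid": -5.0, "slope": 0.8},
    "5FU": {"bottom": 0.30, "top": 1.0, "xmid": -4.8, "slope": 1.0},
    "olaparib": {"bottom": 0.50, "top": 1.0, "xmid": -5.2, "slope": 0.9},
}

#: Caliper schedule: three measurements per week over a 28-day study.
_DEFAULT_DAYS = (0, 2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28)


def default_core_glycans() -> list[str]:
    """The planted 57-glycan core: 5 high-mannose, 3 pauci-mannose, 7 hybrid
    and 42 complex compositions (the subtype split reported for the recurrent
    core in PDAC PDX/organoid profiling)."""
    high_mannose = ["H5N2", "H6N2", "H7N2", "H8N2", "H9N2"]
    pauci = ["H3N2", "H2N2F1", "H3N2F1"]
    hybrid = ["H5N3", "H6N3", "H7N3", "H5N3S1", "H6N3S1", "H5N3F1", "H6N3F1"]
    complex_: list[str] = ["H3N4F1", "H3N3F1"]
    for n, h, f, s in itertools.product((4, 5, 6), (3, 4, 5, 6, 7), (0, 1, 2), (0, 1, 2)):
        comp = GlycanComposition(H=h, N=n, F=f, S=s)
        name = comp.canonical()
        if name in complex_:
            continue
        if classify_subtype(comp).subtype != "complex":
            continue
        complex_.append(name)
        if len(complex_) == 42:
            break
    core = high_mannose + pauci + hybrid + complex_
    assert len(core) == 57
    return core


@dataclass
class SimulationConfig:
    """Planted parameters for all synthetic input kinds.

    The defaults mirror the study design being emulated: viability assayed
    over five logs of dose (10 nM to 100 uM) in replicate, 28-day PDX studies
    with thrice-weekly caliper reads, 5 matched PDX/PXO glycan profiles with
    a 57-glycan core, and a 6-tumor-line EV matrix against an exocrine
    reference.
    """

    seed: int = 0
    # dose-response
    n_doses: int = 9
    n_replicates: int = 3
    noise_sd: float = 0.05
    dose_range_log10: tuple[float, float] = (-8.0, -4.0)
    planted_logistic_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LOGISTIC_PARAMS.items()}
    )
    line_ids: tuple[str, ...] = ("PXO1",)
    # PDX growth
    planted_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"gemcitabine+paclitaxel": 0.25,
                                 "5FU+oxaliplatin": 0.85}
    )
    n_animals: int = 4
    days: tuple[int, ...] = _DEFAULT_DAYS
    baseline_volume_mm3: float = 225.0
    control_growth_rate: float = float(np.log(4.0) / 28.0)  # per day
    growth_noise_sd: float = 0.10
    # glycomics
    core_glycans: list[str] = field(default_factory=default_core_glycans)
    n_variable_glycans: int = 227
    n_glycan_pairs: int = 5
    variable_presence_p: float = 0.37
    pair_effect_sd: float = 0.4
    glycan_noise_sd: float = 0.5
    # EV proteomics + blots
    n_proteins: int = 300
    n_lines: int = 6
    n_reference: int = 2
    planted_marker_ids: tuple[str, ...] = ("CD44", "GPC4", "VGLUT2", "CD14", "ANXA11")
    planted_marker_fold: float = 4.0
    ev_noise_sd: float = 0.15
    blot_n_per_cohort: int = 6
    blot_cohorts: tuple[str, str] = ("GIB", "PDAC")
    shifted_markers: tuple[str, ...] = ("ANXA11", "GPC4", "CD44")
    planted_cohort_shift: float = 4.0
    # AUC cohort with planted sensitivity threshold
    auc_cluster_means: tuple[float, ...] = (0.15, 0.38, 0.61, 0.84)
    auc_cluster_sd: float = 0.04
    auc_per_cluster: int = 6
    planted_threshold: float = 0.52

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.dose_range_log10
        if not lo < hi:
            raise ValueError("dose_range_log10 low must be < high")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(e < 0 for e in self.planted_effect_sizes.values()):
            raise ValueError("growth effect sizes must be >= 0")
        if len(self.days) != len(set(self.days)) or list(self.days) != sorted(self.days):
            raise ValueError("measurement days must be strictly increasing")
        for g in self.core_glycans:
            parse_composition(g)  # raises on malformed strings

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("dose_range_log10", "line_ids", "days", "planted_marker_ids",
                    "blot_cohorts", "shifted_markers", "auc_cluster_means"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _logistic(x, p):
    return p["bottom"] + (p["top"] - p["bottom"]) / (
        1.0 + 10.0 ** (p["slope"] * (x - p["xmid"]))
    ) ** p.get("asymmetry", 1.0)


def gen_dose_response(config: SimulationConfig) -> list[DoseResponsePlate]:
    """Viability plates around the planted logistic curves.

    Viability = planted curve + Gaussian noise (sd ``noise_sd``), truncated
    to [0, 1.5]; the untreated reference is the planted mean of 1.0.
    """
    rng = config.rng()
    lo, hi = config.dose_range_log10
    doses = np.linspace(lo, hi, config.n_doses)
    plates = []
    for line_id in config.line_ids:
        for drug, params in config.planted_logistic_params.items():
            truth = _logistic(doses, params)
            xs, ys = [], []
            for d, t in zip(doses, truth):
                v = t + rng.normal(0.0, config.noise_sd, size=config.n_replicates)
                ys.append(np.clip(v, 0.0, 1.5))
                xs.append(np.full(config.n_replicates, d))
            plates.append(DoseResponsePlate(
                line_id=line_id, drug=drug,
                doses=np.concatenate(xs), viability=np.concatenate(ys),
                untreated_mean=1.0,
            ))
    return plates


def gen_pdx_growth(config: SimulationConfig) -> pd.DataFrame:
    """Caliper table for a control arm plus each planted treatment arm.

    Per-animal volume follows V0 * exp(r * t) * (1 + eps) with control rate
    ``control_growth_rate`` and treated rate scaled by the planted effect;
    length = width = (2V)^(1/3) so the ellipsoid formula recovers V exactly.
    """
    rng = config.rng()
    arms = {"control": 1.0, **config.planted_effect_sizes}
    rows = []
    for arm, effect in arms.items():
        rate = config.control_growth_rate * effect
        for i in range(config.n_animals):
            aid = f"{arm}-m{i + 1}"
            for day in config.days:
                v = config.baseline_volume_mm3 * np.exp(rate * day)
                eps = rng.normal(0.0, config.growth_noise_sd)
                v *= max(0.05, 1.0 + eps)
                lw = (2.0 * v) ** (1.0 / 3.0)
                rows.append({"animal_id": aid, "arm": arm, "day": day,
                             "length_mm": lw, "width_mm": lw})
    return pd.DataFrame(rows)


def gen_glycan_profiles(
    config: SimulationConfig,
) -> tuple[list[GlycanProfile], dict[str, str]]:
    """Matched PDX/PXO glycan profiles with a planted always-present core.

    Core glycans appear in every sample (higher abundance); each variable
    glycan appears per-sample with probability ``variable_presence_p`` (and
    is never allowed to appear in all samples, keeping the planted core
    exact).  log-intensities are Gaussian with a per-glycan level, a shared
    per-matched-pair effect (sd ``pair_effect_sd``) and sample noise.
    """
    rng = config.rng()
    core = [parse_composition(g) for g in config.core_glycans]
    variable = _variable_glycans(config, exclude={c.canonical() for c in core})
    n_pairs = config.n_glycan_pairs
    pairing = {f"PDX{i + 1}": f"PXO{i + 1}" for i in range(n_pairs)}
    sample_ids = list(pairing) + list(pairing.values())
    n_samples = len(sample_ids)

    base_core = rng.normal(np.log(50.0), 1.0, size=len(core))
    base_var = rng.normal(np.log(5.0), 1.0, size=len(variable))
    presence = rng.random((len(variable), n_samples)) < config.variable_presence_p
    all_present = presence.all(axis=1)
    if all_present.any():  # keep the planted core exactly the core set
        drop_cols = rng.integers(0, n_samples, size=int(all_present.sum()))
        presence[np.flatnonzero(all_present), drop_cols] = False

    pair_fx_core = rng.normal(0.0, config.pair_effect_sd, size=(len(core), n_pairs))
    pair_fx_var = rng.normal(0.0, config.pair_effect_sd, size=(len(variable), n_pairs))

    profiles = []
    for j, sid in enumerate(sample_ids):
        pair_idx = j % n_pairs
        source = "PDX" if j < n_pairs else "PXO"
        intens: dict[GlycanComposition, float] = {}
        for gi, comp in enumerate(core):
            logi = (base_core[gi] + pair_fx_core[gi, pair_idx]
                    + rng.normal(0.0, config.glycan_noise_sd))
            intens[comp] = float(np.exp(logi))
        for gi, comp in enumerate(variable):
            if presence[gi, j]:
                logi = (base_var[gi] + pair_fx_var[gi, pair_idx]
                        + rng.normal(0.0, config.glycan_noise_sd))
                intens[comp] = float(np.exp(logi))
        profiles.append(GlycanProfile(sample_id=sid, source=source,
                                      intensities=intens))
    return profiles, pairing


def _variable_glycans(config: SimulationConfig, exclude: set[str]) -> list[GlycanComposition]:
    out = []
    for n, h, f, s in itertools.product(range(2, 8), range(2, 10),
                                        range(0, 4), range(0, 4)):
        comp = GlycanComposition(H=h, N=n, F=f, S=s)
        if comp.canonical() in exclude:
            continue
        out.append(comp)
        if len(out) == config.n_variable_glycans:
            return out
    raise ValueError("n_variable_glycans exceeds the enumerable composition space")


@dataclass
class EVTables:
    matrix: pd.DataFrame               # proteins x samples
    roles: dict[str, str]              # sample -> "tumor" | "reference"
    blot: pd.DataFrame                 # markers (+ CD9 row) x patients
    cohorts: dict[str, str]            # patient -> cohort label


def gen_ev_tables(config: SimulationConfig) -> EVTables:
    """EV protein matrix with planted enriched markers, plus a blot table.

    Planted markers are elevated ``planted_marker_fold``-fold in every tumor
    line over the exocrine reference; background proteins share a common
    level across all samples up to lognormal noise.  The blot table has a
    strictly positive CD9 row and a planted multiplicative cohort shift for
    ``shifted_markers`` in the second cohort.
    """
    rng = config.rng()
    if config.n_lines < 4:
        raise ValueError("need at least 4 tumor lines for the prevalence filter")
    markers = list(config.planted_marker_ids)
    n_bg = config.n_proteins - len(markers)
    if n_bg < 0:
        raise ValueError("n_proteins smaller than the planted marker set")
    proteins = markers + [f"P{i + 1:04d}" for i in range(n_bg)]
    tumor_cols = [f"PXO{i + 1}" for i in range(config.n_lines)]
    ref_cols = [f"EXO{i + 1}" for i in range(config.n_reference)]
    roles = {c: "tumor" for c in tumor_cols} | {c: "reference" for c in ref_cols}

    base = np.exp(rng.normal(np.log(1e4), 1.0, size=len(proteins)))
    noise = np.exp(rng.normal(0.0, config.ev_noise_sd,
                              size=(len(proteins), len(tumor_cols) + len(ref_cols))))
    x = base[:, None] * noise
    x[:len(markers), :len(tumor_cols)] *= config.planted_marker_fold
    matrix = pd.DataFrame(x, index=proteins, columns=tumor_cols + ref_cols)

    # blot table: cohorts x patients, CD9 loading control
    ga, gb = config.blot_cohorts
    patients = ([f"{ga}{i + 1}" for i in range(config.blot_n_per_cohort)]
                + [f"{gb}{i + 1}" for i in range(config.blot_n_per_cohort)])
    cohorts = {p: (ga if p.startswith(ga) else gb) for p in patients}
    cd9 = np.exp(rng.normal(np.log(100.0), 0.3, size=len(patients)))
    rows = {"CD9": cd9}
    for m in markers:
        ratio = np.exp(rng.normal(np.log(0.5), 0.4, size=len(patients)))
        if m in config.shifted_markers:
            shift = np.ones(len(patients))
            shift[config.blot_n_per_cohort:] = config.planted_cohort_shift
            ratio = ratio * shift
        rows[m] = ratio * cd9
    blot = pd.DataFrame(rows, index=patients).T
    return EVTables(matrix=matrix, roles=roles, blot=blot, cohorts=cohorts)


@dataclass
class AUCCohort:
    values: np.ndarray            # normalized AUCs, generation order
    responder: np.ndarray         # bool; True where the planted truth is sensitive
    cluster: np.ndarray           # planted cluster index per value
    threshold: float              # planted sensitivity threshold

    def sorted(self) -> "AUCCohort":
        order = np.argsort(self.values, kind="stable")
        return AUCCohort(self.values[order], self.responder[order],
                         self.cluster[order], self.threshold)


def gen_auc_cohort(config: SimulationConfig) -> AUCCohort:
    """Normalized-AUC cohort with a planted sensitivity threshold.

    Values are drawn around ``auc_cluster_means`` (Gaussian, sd
    ``auc_cluster_sd``, clipped to (0, 1)); the in vivo responder label is
    the planted truth: cluster mean below ``planted_threshold``.
    """
    rng = config.rng()
    means = np.asarray(config.auc_cluster_means, dtype=float)
    values, resp, clusters = [], [], []
    for ci, m in enumerate(means):
        draw = rng.normal(m, config.auc_cluster_sd, size=config.auc_per_cluster)
        values.append(np.clip(draw, 0.01, 0.99))
        resp.append(np.full(config.auc_per_cluster, m < config.planted_threshold))
        clusters.append(np.full(config.auc_per_cluster, ci))
    return AUCCohort(values=np.concatenate(values),
                     responder=np.concatenate(resp),
                     cluster=np.concatenate(clusters),
                     threshold=config.planted_threshold)
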