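"""Seeded generators for synthetic Match/Mismatch cohorts.

The study's animal-level data are not publicly deposited, so every analysis
stage in this package is exercised on synthetic cohorts that carry the
statistical structure the analysis assumes:

* two-group (Match/Mismatch) pigs with LAD-territory infarcts; Mismatch
  animals show high day-3 FDG uptake co-located with high transmurality,
  Match animals show an uptake defect over the same scar;
* global CMR parameters (EF, EDV, infarct size, glucose) drawn from the
  printed group means and SDs;
* circulating cytokines and qPCR Ct panels;
* bulk counts with additive immune-signature structure scaled by group and
  region;
* single-nucleus counts with cell-type marker structure, mitochondrial
  fractions, library-size variation and hashtag-oligo counts.

Continuous imaging quantities use truncated normal draws (percents bounded
to [0, 100]).  The location parameter is adjusted so that the *truncated*
mean equals the configured mean; without this correction a strongly
truncated quantity such as the month-1 infarct uptake (56.0 +/- 23.1 on
[0, 100]) would systematically miss its configured mean.

One global seed feeds a hierarchy of named substreams (``numpy``
``SeedSequence`` children), so each output block can be regenerated
independently and all generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import optimize
from scipy import stats as st

from .errors import ConfigError
from .polarmap import (
    CONTRACTILITY_FLOOR,
    LAD_TERRITORY,
    N_SEGMENTS,
    SegmentProfile,
    Territory,
)
from .signatures import CELL_TYPE_SIGNATURES, IMMUNE_SIGNATURES, MITO_GENES, SignatureSet

GROUPS = ("Match", "Mismatch")
REGIONS = ("AMI", "Border", "Remote")
BIOMARKER_TIMEPOINTS = ("baseline", "post_ami_30min", "day3")

MeanSd = tuple[float, float]


# ---------------------------------------------------------------------------
# truncated-normal primitive


def _truncated_mean(loc: float, sd: float, low: float, high: float) -> float:
    a, b = (low - loc) / sd, (high - loc) / sd
    return float(st.truncnorm.mean(a, b, loc=loc, scale=sd))


def solve_truncnorm_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter such that a TruncNormal(loc, sd) on [low, high]
    has expectation ``mean``.  Requires low < mean < high."""
    if not low < mean < high:
        raise ConfigError(
            f"target mean {mean} must lie strictly inside bounds ({low}, {high})"
        )
    f = lambda loc: _truncated_mean(loc, sd, low, high) - mean
    lo, hi = mean - 2 * sd, mean + 2 * sd
    for _ in range(12):
        if f(lo) < 0:
            break
        lo -= 2 * sd
    for _ in range(12):
        if f(hi) > 0:
            break
        hi += 2 * sd
    if not (f(lo) < 0 < f(hi)):
        raise ConfigError(
            f"cannot match mean {mean} with sd {sd} on [{low}, {high}] (truncation too severe)"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def truncated_normal(
    rng: Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    size,
    match_mean: bool = True,
) -> np.ndarray:
    """Draw from a normal truncated to [low, high].

    With ``match_mean`` (the default) the underlying location is adjusted so
    the truncated distribution's expectation equals ``mean`` exactly.
    """
    if sd < 0:
        raise ConfigError("sd must be nonnegative")
    if low >= high:
        raise ConfigError(f"impossible truncation bounds [{low}, {high}]")
    if sd == 0:
        if not low <= mean <= high:
            raise ConfigError(f"point mass {mean} outside bounds [{low}, {high}]")
        return np.full(size, float(mean))
    loc = solve_truncnorm_loc(mean, sd, low, high) if match_mean else mean
    a, b = (low - loc) / sd, (high - loc) / sd
    return st.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _check_meansd(name: str, ms: Mapping[str, MeanSd] | MeanSd) -> None:
    pairs = ms.values() if isinstance(ms, Mapping) else [ms]
    for m, s in pairs:
        if s < 0:
            raise ConfigError(f"{name}: sd must be nonnegative (got {s})")


# ---------------------------------------------------------------------------
# cohort-level config and generator


def _paper_group_stat(match: MeanSd, mismatch: MeanSd) -> dict[str, MeanSd]:
    return {"Match": match, "Mismatch": mismatch}


@dataclass
class CohortConfig:
    """Distributional description of a synthetic imaging cohort.

    Group-level means/SDs of EF, infarct size, month-1 infarct-territory
    uptake, fasting glucose and the TIMI-2 shares are the values printed for
    the study cohort.  Quantities the study never prints numerically
    (day-3 territory uptake levels, transmurality and contractility spreads,
    EDV, biomarker panels) carry documented placeholder defaults chosen to
    reproduce the qualitative phenotypes.
    """

    n_match: int = 22
    n_mismatch: int = 8
    seed: int = 0

    # printed group distributions (percent; EDV in mL; glucose in mg/dL)
    ef_day3: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((42.0, 5.2), (34.0, 8.7))
    )
    ef_month1: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((43.0, 6.3), (35.8, 9.5))
    )
    infarct_day3: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((22.1, 4.4), (26.6, 6.6))
    )
    infarct_month1: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((20.3, 7.2), (28.0, 10.4))
    )
    uptake_infarct_month1: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((64.7, 13.2), (56.0, 23.1))
    )
    glucose: MeanSd = (105.0, 8.0)
    timi2_rate: dict[str, float] = field(
        default_factory=lambda: {"Match": 3 / 25, "Mismatch": 1 / 12}
    )
    blush2_rate: dict[str, float] = field(
        default_factory=lambda: {"Match": 2 / 25, "Mismatch": 1 / 12}
    )

    # placeholder distributions (not printed in the study)
    uptake_infarct_day3: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((45.0, 12.0), (85.0, 7.0))
    )
    transmurality_infarct: MeanSd = (85.0, 7.0)
    transmurality_remote: MeanSd = (4.0, 4.0)
    uptake_remote: MeanSd = (82.0, 8.0)
    edv_day3: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((105.0, 18.0), (108.0, 20.0))
    )
    edv_month1: dict[str, MeanSd] = field(
        default_factory=lambda: _paper_group_stat((112.0, 18.0), (124.0, 26.0))
    )
    mvo: MeanSd = (4.0, 3.0)
    #: linear dependence of MVO on day-3 territory uptake; 0 = independent
    mvo_uptake_coupling: float = 0.0
    contractility_infarct_day3: MeanSd = (2.0, 8.0)
    contractility_remote_day3: MeanSd = (35.0, 10.0)
    #: month-1 contractility = intercept + slope * uptake_norm + noise
    contractility_month1_intercept: float = -20.0
    contractility_month1_slope: float = 0.6
    contractility_month1_noise_sd: float = 8.0

    infarct_territory: Territory = field(default_factory=lambda: LAD_TERRITORY)
    #: remote segment pinned to 100% (the hottest, reference segment)
    reference_segment: int = 6

    # biomarker panels: gene-agnostic per (analyte, timepoint, group) means
    il6: dict[str, dict[str, MeanSd]] = field(
        default_factory=lambda: {
            "baseline": _paper_group_stat((20.0, 8.0), (20.0, 8.0)),
            "post_ami_30min": _paper_group_stat((35.0, 15.0), (40.0, 15.0)),
            "day3": _paper_group_stat((60.0, 20.0), (95.0, 25.0)),
        }
    )
    il1b: dict[str, dict[str, MeanSd]] = field(
        default_factory=lambda: {
            "baseline": _paper_group_stat((15.0, 5.0), (15.0, 5.0)),
            "post_ami_30min": _paper_group_stat((20.0, 8.0), (22.0, 8.0)),
            "day3": _paper_group_stat((24.0, 9.0), (28.0, 10.0)),
        }
    )

    # qPCR: reference and target base Ct, and expression shifts (delta Ct,
    # negative = higher expression) per (gene, region, group)
    ct_reference: dict[str, MeanSd] = field(
        default_factory=lambda: {"HPRT": (20.0, 0.3), "ACTB": (19.0, 0.3)}
    )
    ct_target_base: dict[str, MeanSd] = field(
        default_factory=lambda: {"CD45": (26.5, 0.4), "CD68": (27.5, 0.4), "TNFa": (30.0, 0.4)}
    )
    ct_shift: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "CD68": {
                ("AMI", "Mismatch"): -2.0,
                ("AMI", "Match"): -1.4,
                ("Border", "Mismatch"): -1.0,
                ("Border", "Match"): -0.6,
            },
            "CD45": {
                ("AMI", "Mismatch"): 0.3,
                ("AMI", "Match"): 0.0,
                ("Border", "Mismatch"): 0.2,
                ("Border", "Match"): 0.0,
            },
            "TNFa": {},
        }
    )
    #: per-sample technical Ct offset SD (applies to every gene of a sample)
    ct_sample_shift_sd: float = 0.3
    n_controls: int = 3

    def __post_init__(self) -> None:
        if self.n_match < 0 or self.n_mismatch < 0:
            raise ConfigError("group sizes must be nonnegative")
        if self.n_match + self.n_mismatch < 2:
            raise ConfigError("n_match + n_mismatch must be at least 2")
        for name in (
            "ef_day3", "ef_month1", "infarct_day3", "infarct_month1",
            "uptake_infarct_month1", "uptake_infarct_day3", "edv_day3", "edv_month1",
        ):
            _check_meansd(name, getattr(self, name))
        for name in ("glucose", "transmurality_infarct", "transmurality_remote",
                     "uptake_remote", "mvo", "contractility_infarct_day3",
                     "contractility_remote_day3"):
            _check_meansd(name, getattr(self, name))
        if self.reference_segment in self.infarct_territory.segment_ids:
            raise ConfigError("reference segment must lie outside the infarct territory")


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    animals: pd.DataFrame
    profiles: list[SegmentProfile]
    biomarkers: pd.DataFrame
    ct: pd.DataFrame
    config: CohortConfig
    seed: int

    def profile(self, animal_id: str, timepoint: str) -> SegmentProfile:
        for p in self.profiles:
            if p.animal_id == animal_id and p.timepoint == timepoint:
                return p
        raise KeyError((animal_id, timepoint))

    def profiles_at(self, timepoint: str) -> list[SegmentProfile]:
        return [p for p in self.profiles if p.timepoint == timepoint]


def _group_draw(
    rng: Generator,
    groups: np.ndarray,
    spec: Mapping[str, MeanSd],
    low: float,
    high: float,
) -> np.ndarray:
    out = np.empty(groups.shape[0])
    for g in GROUPS:
        sel = groups == g
        if sel.any():
            m, s = spec[g]
            out[sel] = truncated_normal(rng, m, s, low, high, int(sel.sum()))
    return out


def simulate_cohort(cfg: CohortConfig, seed: int | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort: animal records, day-3 and month-1
    segment profiles, and biomarker panels.  Pure function of (cfg, seed)."""
    seed = cfg.seed if seed is None else int(seed)
    ss = SeedSequence(seed)
    streams = {
        name: default_rng(child)
        for name, child in zip(
            ("globals", "segments_day3", "segments_month1", "biomarkers", "qpcr"),
            ss.spawn(5),
        )
    }

    n = cfg.n_match + cfg.n_mismatch
    groups = np.array(["Match"] * cfg.n_match + ["Mismatch"] * cfg.n_mismatch)
    animal_ids = np.array([f"P{i + 1:04d}" for i in range(n)])

    rng = streams["globals"]
    animals = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "group_intended": groups,
            "glucose": truncated_normal(rng, *cfg.glucose, 20.0, 400.0, n),
            "ef_day3": _group_draw(rng, groups, cfg.ef_day3, 0.0, 100.0),
            "ef_month1": _group_draw(rng, groups, cfg.ef_month1, 0.0, 100.0),
            "edv_day3": _group_draw(rng, groups, cfg.edv_day3, 20.0, 400.0),
            "edv_month1": _group_draw(rng, groups, cfg.edv_month1, 20.0, 400.0),
            "infarct_day3": _group_draw(rng, groups, cfg.infarct_day3, 0.0, 100.0),
            "infarct_month1": _group_draw(rng, groups, cfg.infarct_month1, 0.0, 100.0),
        }
    )
    timi2 = np.array([rng.random() < cfg.timi2_rate[g] for g in groups])
    blush2 = np.array([rng.random() < cfg.blush2_rate[g] for g in groups])
    animals["timi_flow"] = np.where(timi2, 2, 3)
    animals["blush_grade"] = np.where(blush2, 2, 3)

    territory_idx = cfg.infarct_territory.indices()
    remote_idx = np.setdiff1d(np.arange(N_SEGMENTS), territory_idx)
    ref_idx = cfg.reference_segment - 1

    profiles: list[SegmentProfile] = []
    mvo_all: np.ndarray | None = None
    for timepoint in ("day3", "month1"):
        rng_t = streams[f"segments_{timepoint}"]
        tm = np.empty((n, N_SEGMENTS))
        up = np.empty((n, N_SEGMENTS))
        tm[:, territory_idx] = truncated_normal(
            rng_t, *cfg.transmurality_infarct, 0.0, 100.0, (n, len(territory_idx))
        )
        tm[:, remote_idx] = truncated_normal(
            rng_t, *cfg.transmurality_remote, 0.0, 100.0, (n, len(remote_idx))
        )
        uptake_spec = (
            cfg.uptake_infarct_day3 if timepoint == "day3" else cfg.uptake_infarct_month1
        )
        for g in GROUPS:
            sel = np.flatnonzero(groups == g)
            if sel.size:
                m, s = uptake_spec[g]
                up[np.ix_(sel, territory_idx)] = truncated_normal(
                    rng_t, m, s, 0.0, 100.0, (sel.size, len(territory_idx))
                )
        up[:, remote_idx] = truncated_normal(
            rng_t, *cfg.uptake_remote, 0.0, 100.0, (n, len(remote_idx))
        )
        up[:, ref_idx] = 100.0  # hottest remote segment, normalization reference

        if timepoint == "day3":
            ct = np.empty((n, N_SEGMENTS))
            ct[:, territory_idx] = truncated_normal(
                rng_t, *cfg.contractility_infarct_day3,
                CONTRACTILITY_FLOOR, 100.0, (n, len(territory_idx)),
            )
            ct[:, remote_idx] = truncated_normal(
                rng_t, *cfg.contractility_remote_day3,
                CONTRACTILITY_FLOOR, 100.0, (n, len(remote_idx)),
            )
            terr_up_mean = up[:, territory_idx].mean(axis=1)
            mvo = truncated_normal(rng_t, *cfg.mvo, 0.0, 100.0, n)
            if cfg.mvo_uptake_coupling != 0.0:
                mvo = np.clip(
                    mvo + cfg.mvo_uptake_coupling * (terr_up_mean - terr_up_mean.mean()),
                    0.0, 100.0,
                )
            mvo_all = mvo
        else:
            noise = rng_t.normal(0.0, cfg.contractility_month1_noise_sd, (n, N_SEGMENTS))
            ct = np.clip(
                cfg.contractility_month1_intercept
                + cfg.contractility_month1_slope * up
                + noise,
                CONTRACTILITY_FLOOR, 100.0,
            )
            mvo = mvo_all  # MVO is a day-3 CMR finding; carried over unchanged

        raw_scale = rng_t.lognormal(mean=np.log(0.5), sigma=0.2, size=n)
        for i in range(n):
            profiles.append(
                SegmentProfile(
                    animal_id=animal_ids[i],
                    timepoint=timepoint,
                    transmurality=tm[i],
                    uptake_raw=up[i] * raw_scale[i],
                    contractility=ct[i],
                    mvo_extent=float(mvo[i]),
                )
            )
    animals["mvo_extent"] = mvo_all

    # circulating cytokines
    rng_b = streams["biomarkers"]
    rows = []
    for tp in BIOMARKER_TIMEPOINTS:
        il6 = _group_draw(rng_b, groups, cfg.il6[tp], 0.0, 1e4)
        il1b = _group_draw(rng_b, groups, cfg.il1b[tp], 0.0, 1e4)
        for i in range(n):
            rows.append(
                {"animal_id": animal_ids[i], "timepoint": tp,
                 "il1b": il1b[i], "il6": il6[i]}
            )
    biomarkers = pd.DataFrame(rows)

    # tissue qPCR panels (AMI + border per animal, plus healthy controls)
    rng_q = streams["qpcr"]
    ct_rows = []
    samples = [(a, g, r) for a, g in zip(animal_ids, groups) for r in ("AMI", "Border")]
    samples += [(f"C{i + 1:03d}", "Control", "Control") for i in range(cfg.n_controls)]
    for animal, group, region in samples:
        sample_shift = rng_q.normal(0.0, cfg.ct_sample_shift_sd)
        for gene, (m, s) in {**cfg.ct_reference, **cfg.ct_target_base}.items():
            shift = cfg.ct_shift.get(gene, {}).get((region, group), 0.0)
            ct_val = rng_q.normal(m + shift + sample_shift, s)
            ct_rows.append(
                {"animal_id": animal, "group": group, "region": region,
                 "gene": gene, "ct": float(np.clip(ct_val, 10.0, 40.0))}
            )
    ct_table = pd.DataFrame(ct_rows)

    return SimulatedCohort(animals, profiles, biomarkers, ct_table, cfg, seed)


# ---------------------------------------------------------------------------
# bulk expression generator


@dataclass
class BulkConfig:
    """Negative-binomial bulk RNA generator with additive immune-signature
    structure: marker genes of cell type t in sample s have their mean
    multiplied by (1 + effect[t][(group, region)])."""

    n_background_genes: int = 800
    base_mean_log: float = np.log(30.0)
    base_mean_sigma: float = 1.0
    libsize_sigma: float = 0.3
    nb_dispersion: float = 10.0  # gamma shape; larger = closer to Poisson
    signatures: SignatureSet = field(default_factory=lambda: IMMUNE_SIGNATURES)
    effects: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "Monocytes": {("Mismatch", "AMI"): 2.0, ("Mismatch", "Border"): 1.0,
                          ("Match", "AMI"): 0.8, ("Match", "Border"): 0.3},
            "Macrophages": {("Mismatch", "AMI"): 2.0, ("Mismatch", "Border"): 1.0,
                            ("Match", "AMI"): 0.9, ("Match", "Border"): 0.3},
            "Neutrophils": {("Mismatch", "AMI"): 1.0, ("Mismatch", "Border"): 0.5,
                            ("Match", "AMI"): 0.5, ("Match", "Border"): 0.2},
            "T cells": {("Mismatch", "AMI"): 0.6, ("Mismatch", "Border"): 0.3,
                        ("Match", "AMI"): 0.3, ("Match", "Border"): 0.1},
            "NK cells": {("Mismatch", "AMI"): 0.6, ("Mismatch", "Border"): 0.4,
                         ("Match", "AMI"): 0.2, ("Match", "Border"): 0.1},
            "B cells": {("Mismatch", "AMI"): 0.5, ("Mismatch", "Border"): 0.3,
                        ("Match", "AMI"): 0.2, ("Match", "Border"): 0.1},
        }
    )
    #: substream used for the (sample-independent) gene baseline, so that
    #: different arms simulated separately share one gene universe
    gene_seed: int = 911

    def __post_init__(self) -> None:
        if self.n_background_genes < 1:
            raise ConfigError("need at least one background gene")
        sig_genes = set(self.signatures.genes())
        bg = {f"G{i + 1:04d}" for i in range(self.n_background_genes)}
        if sig_genes & bg:
            raise ConfigError("signature genes must be disjoint from background genes")
        for t in self.effects:
            if t not in self.signatures.signatures:
                raise ConfigError(f"effect configured for unknown cell type {t!r}")


@dataclass
class BulkExperiment:
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    sample_meta: pd.DataFrame  # index sample_id, columns group/region


DEFAULT_BULK_ARMS: tuple[tuple[str, str], ...] = (
    ("Match", "AMI"), ("Match", "Border"),
    ("Mismatch", "AMI"), ("Mismatch", "Border"),
    ("Control", "Remote"),
)


def simulate_bulk_expression(
    cfg: BulkConfig,
    arms: Sequence[tuple[str, str]] = DEFAULT_BULK_ARMS,
    n_per_arm: int = 3,
    seed: int = 0,
) -> BulkExperiment:
    """Simulate a gene x sample count table over (group, region) arms."""
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_background_genes)]
    genes += cfg.signatures.genes()
    gene_index = {g: i for i, g in enumerate(genes)}

    base_rng = default_rng(SeedSequence(cfg.gene_seed))
    base_mean = base_rng.lognormal(cfg.base_mean_log, cfg.base_mean_sigma, len(genes))

    rng = default_rng(SeedSequence(int(seed)))
    sample_ids, meta_rows, cols = [], [], []
    for group, region in arms:
        fold = np.ones(len(genes))
        for cell_type, eff in cfg.effects.items():
            e = eff.get((group, region), 0.0)
            if e:
                for g in cfg.signatures[cell_type]:
                    fold[gene_index[g]] *= 1.0 + e
        for k in range(n_per_arm):
            sid = f"{group}_{region}_{k + 1}"
            lib = rng.lognormal(0.0, cfg.libsize_sigma)
            mu = base_mean * fold * lib
            # NB via gamma-Poisson mixture
            lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
            cols.append(rng.poisson(lam))
            sample_ids.append(sid)
            meta_rows.append({"group": group, "region": region})
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return BulkExperiment(counts, meta)


# ---------------------------------------------------------------------------
# single-nucleus generator


def _nuclei_proportions() -> dict[tuple[str, str], dict[str, float]]:
    """Cell-type mixing proportions per (region, group), shaped after the
    study's count table: border-zone Mismatch tissue is rich in monocytes
    (5% vs 1% in Match), NK cells and macrophages; the infarct core is
    immune-poor in the sequencing data for technical reasons."""

    def comp(**kw: float) -> dict[str, float]:
        rest = 1.0 - sum(kw.values())
        if rest <= 0:
            raise ConfigError("cell-type proportions exceed 1")
        return {"Cardiomyocytes": round(rest, 6), **kw}

    return {
        ("Border", "Match"): comp(
            Fibroblasts=0.25, **{"Endothelial cells": 0.11, "Pericytes": 0.05,
                                 "Smooth muscle cells": 0.016},
            Monocytes=0.010, Macrophages=0.002, Neutrophils=0.002,
            **{"T cells": 0.005, "NK cells": 0.003, "B cells": 0.002},
        ),
        ("Border", "Mismatch"): comp(
            Fibroblasts=0.21, **{"Endothelial cells": 0.10, "Pericytes": 0.05,
                                 "Smooth muscle cells": 0.02},
            Monocytes=0.050, Macrophages=0.020, Neutrophils=0.005,
            **{"T cells": 0.015, "NK cells": 0.040, "B cells": 0.030},
        ),
        ("Remote", "Match"): comp(
            Fibroblasts=0.22, **{"Endothelial cells": 0.10, "Pericytes": 0.045,
                                 "Smooth muscle cells": 0.018},
            Monocytes=0.010, Macrophages=0.013, Neutrophils=0.001,
            **{"T cells": 0.002, "NK cells": 0.010, "B cells": 0.002},
        ),
        ("Remote", "Mismatch"): comp(
            Fibroblasts=0.22, **{"Endothelial cells": 0.10, "Pericytes": 0.045,
                                 "Smooth muscle cells": 0.018},
            Monocytes=0.013, Macrophages=0.018, Neutrophils=0.005,
            **{"T cells": 0.002, "NK cells": 0.012, "B cells": 0.002},
        ),
        ("AMI", "Match"): comp(
            Fibroblasts=0.32, **{"Endothelial cells": 0.09, "Pericytes": 0.04,
                                 "Smooth muscle cells": 0.02},
            Monocytes=0.002, Macrophages=0.004, Neutrophils=0.005,
            **{"T cells": 0.010, "NK cells": 0.002, "B cells": 0.006},
        ),
        ("AMI", "Mismatch"): comp(
            Fibroblasts=0.34, **{"Endothelial cells": 0.08, "Pericytes": 0.04,
                                 "Smooth muscle cells": 0.02},
            Monocytes=0.005, Macrophages=0.012, Neutrophils=0.012,
            **{"T cells": 0.015, "NK cells": 0.005, "B cells": 0.012},
        ),
    }


@dataclass
class NucleiConfig:
    """Single-nucleus count generator.

    Each nucleus draws a latent cell type from the (region, group)
    proportions, up-scales its type's marker genes, receives mitochondrial
    counts matching a region-specific Beta-distributed fraction (heavier
    tail in the infarct core), a log-normal library size spanning the
    200-detected-genes QC boundary, and hashtag-oligo counts from a
    background/signal log-normal mixture with latent sample identity.
    """

    n_background_genes: int = 300
    signatures: SignatureSet = field(default_factory=lambda: CELL_TYPE_SIGNATURES)
    proportions: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_nuclei_proportions
    )
    marker_fold: float = 80.0
    marker_base_weight: float = 0.5
    lib_mean_log: float = np.log(1200.0)
    lib_sigma: float = 0.6
    #: library-size multiplier per region (infarct nuclei are poorer)
    region_lib_scale: dict[str, float] = field(
        default_factory=lambda: {"AMI": 0.6, "Border": 1.0, "Remote": 1.0}
    )
    #: Beta(a, b) parameters of the mitochondrial fraction per region
    mito_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AMI": (1.6, 8.0), "Border": (2.0, 30.0),
                                 "Remote": (2.0, 40.0)}
    )
    n_hashtags: int = 4
    hashtag_signal_mean: float = 300.0
    hashtag_signal_sigma: float = 0.4
    hashtag_background_mean: float = 8.0
    hashtag_background_sigma: float = 0.6
    gene_seed: int = 911

    def __post_init__(self) -> None:
        for key, props in self.proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"proportions for {key} sum to {total}, not 1")
            unknown = set(props) - set(self.signatures.cell_types)
            if unknown:
                raise ConfigError(f"proportions for {key} name unknown types {unknown}")
        if self.n_hashtags < 2:
            raise ConfigError("need at least 2 hashtags")


def nuclei_gene_universe(cfg: NucleiConfig) -> list[str]:
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_background_genes)]
    genes += cfg.signatures.genes()
    genes += list(MITO_GENES)
    return genes


def simulate_nuclei(
    cfg: NucleiConfig,
    region: str,
    group: str,
    n_cells: int = 1000,
    seed: int = 0,
):
    """Simulate a gene x cell count matrix as an :class:`anndata.AnnData`
    (cells x genes, per convention), with latent type labels, mitochondrial
    fractions and hashtag counts."""
    import anndata as ad
    from scipy import sparse

    if (region, group) not in cfg.proportions:
        raise ConfigError(f"no proportions configured for ({region!r}, {group!r})")
    props = cfg.proportions[(region, group)]
    types = list(props)
    p_types = np.array([props[t] for t in types])

    genes = nuclei_gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    mito_idx = np.array([gene_index[g] for g in MITO_GENES])
    marker_idx = {
        t: np.array([gene_index[g] for g in cfg.signatures[t]])
        for t in cfg.signatures.cell_types
    }
    all_marker_idx = np.concatenate(list(marker_idx.values()))

    base_rng = default_rng(SeedSequence(cfg.gene_seed))
    base_weight = base_rng.gamma(2.0, 0.5, n_genes)
    base_weight[all_marker_idx] = cfg.marker_base_weight
    base_weight[mito_idx] = 0.0  # mitochondrial mass set per cell below

    rng = default_rng(SeedSequence(int(seed)))
    latent = rng.choice(len(types), size=n_cells, p=p_types)
    lib = np.maximum(
        rng.lognormal(cfg.lib_mean_log + np.log(cfg.region_lib_scale.get(region, 1.0)),
                      cfg.lib_sigma, n_cells),
        30.0,
    ).astype(int)
    a, b = cfg.mito_beta[region]
    mito_frac_target = np.clip(rng.beta(a, b, n_cells), 1e-4, 0.9)

    X = np.zeros((n_cells, n_genes), dtype=np.int64)
    for i in range(n_cells):
        w = base_weight.copy()
        w[marker_idx[types[latent[i]]]] *= cfg.marker_fold / cfg.marker_base_weight
        f = mito_frac_target[i]
        w[mito_idx] = f / (1.0 - f) * w.sum() / len(mito_idx)
        X[i] = rng.multinomial(lib[i], w / w.sum())

    totals = X.sum(axis=1)
    obs = pd.DataFrame(
        {
            "region": region,
            "group": group,
            "true_type": [types[j] for j in latent],
            "total_counts": totals,
            "detected_genes": (X > 0).sum(axis=1),
            "mito_fraction": X[:, mito_idx].sum(axis=1) / np.maximum(totals, 1),
        },
        index=[f"{region}_{group}_c{i + 1:05d}" for i in range(n_cells)],
    )

    tags = [f"HTO{k + 1}" for k in range(cfg.n_hashtags)]
    true_tag = rng.integers(cfg.n_hashtags, size=n_cells)
    hto = np.rint(
        rng.lognormal(np.log(cfg.hashtag_background_mean),
                      cfg.hashtag_background_sigma, (n_cells, cfg.n_hashtags))
    )
    signal = np.rint(
        rng.lognormal(np.log(cfg.hashtag_signal_mean),
                      cfg.hashtag_signal_sigma, n_cells)
    )
    hto[np.arange(n_cells), true_tag] = signal
    obs["true_tag"] = [tags[k] for k in true_tag]

    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )
    adata.obsm["hto"] = pd.DataFrame(hto, index=obs.index, columns=tags).astype(int)
    adata.uns["signatures"] = {t: list(g) for t, g in cfg.signatures.signatures.items()}
    return adata
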