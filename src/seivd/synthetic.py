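"""Synthetic experiment generators with the study's sampling designs.

Emulates three dataset shapes from known ground-truth traits:

* one-step growth curves: a 15-min adsorption phase at 10^8 cells/ml and
  MOI 0.1, an instantaneous 1:100 dilution, then free/total phage sampling
  over a single lytic cycle;
* pairwise multi-cycle infections: hosts at 2x10^6 CFU/ml, phage at MOI 0.1,
  sparse qPCR sampling at 0, 3.5 and 15.75 h plus phage-free controls;
* the community experiment: five hosts at 2x10^6 cells/ml each, five phage
  at a flask-wide MOI of 0.1, triplicate qINT/qEXT sampling every 35 min for
  15.75 h (28 points).

Measurement noise is multiplicative log-normal (additive Gaussian on log10
densities) with a detection floor; censored records are flagged, not
dropped.  Every generated dataset carries a provenance manifest with the
design, ground-truth traits and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .models import (
    CommunityModel,
    InfectionMatrix,
    TraitSet,
    integrate_pairwise_state,
    observe,
    simulate_community,
    simulate_pairwise,
)

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "TimeSeriesDataset",
    "sampling_schedule",
    "initial_conditions_from_moi",
    "simulate_onestep_protocol",
    "generate_onestep",
    "generate_pairwise_multicycle",
    "generate_community",
    "scenario_traitshift",
]

SCHEMA = ["time_h", "id", "replicate", "observable", "value", "below_detection"]


def sampling_schedule(interval_h: float, duration_h: float) -> np.ndarray:
    """Regular grid {0, dt, 2dt, ...} up to the last multiple <= duration.

    A 35-min interval over 15.75 h gives 28 points.
    """
    if not interval_h > 0:
        raise ValueError("sampling interval must be > 0")
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    n = int(math.floor(duration_h / interval_h + 1e-9)) + 1
    return np.arange(n) * interval_h


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of one experiment type.

    ``initial_cells`` is a density (cells/ml), either one value (pairwise
    assays) or a per-strain mapping (community).  ``moi`` is phage-to-cell;
    with ``moi_convention = "flask"`` the community MOI is total phage over
    total cells split equally across phage strains, with ``"per_phage"``
    each phage individually is at ``moi`` times total cells.
    """

    initial_cells: float | Mapping[str, float]
    moi: float = 0.1
    sampling_interval_h: float | None = None
    duration_h: float = 0.0
    n_replicates: int = 3
    dilutions: tuple = ()  # ((time_h, factor), ...)
    adsorption_phase_h: float = 0.0
    sample_times_h: tuple | None = None
    moi_convention: str = "flask"

    def __post_init__(self):
        if self.moi < 0:
            raise ValueError("MOI must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.duration_h < 0:
            raise ValueError("duration must be >= 0")
        if self.moi_convention not in ("flask", "per_phage"):
            raise ValueError("moi_convention must be 'flask' or 'per_phage'")
        for t, f in self.dilutions:
            if not 0 < f <= 1:
                raise ValueError("dilution factors must be in (0, 1]")

    @property
    def total_cells(self) -> float:
        if isinstance(self.initial_cells, Mapping):
            return float(sum(self.initial_cells.values()))
        return float(self.initial_cells)

    @property
    def initial_phage(self) -> float:
        """Phage density for a single-phage experiment (virions/ml)."""
        return self.moi * self.total_cells

    @property
    def dilution_factor(self) -> float:
        return self.dilutions[0][1] if self.dilutions else 1.0

    def times(self) -> np.ndarray:
        if self.sample_times_h is not None:
            return np.asarray(self.sample_times_h, dtype=float)
        if self.sampling_interval_h is None:
            raise ValueError("design has neither explicit sample times nor an interval")
        return sampling_schedule(self.sampling_interval_h, self.duration_h)

    # -- canonical study designs ------------------------------------------

    @classmethod
    def onestep(
        cls,
        initial_cells: float = 1e8,
        moi: float = 0.1,
        adsorption_phase_h: float = 0.25,
        dilution_factor: float = 0.01,
        sampling_interval_h: float = 5.0 / 60.0,
        duration_h: float = 2.75,
        n_replicates: int = 3,
    ) -> "ExperimentDesign":
        """One-step protocol: 15-min adsorption, 1:100 dilution, PFU sampling."""
        times = adsorption_phase_h + sampling_schedule(sampling_interval_h, duration_h)
        return cls(
            initial_cells=initial_cells,
            moi=moi,
            n_replicates=n_replicates,
            dilutions=((adsorption_phase_h, dilution_factor),),
            adsorption_phase_h=adsorption_phase_h,
            sample_times_h=tuple(times),
        )

    @classmethod
    def pairwise_multicycle(
        cls,
        initial_cells: float = 2e6,
        moi: float = 0.1,
        sample_times_h: tuple = (0.0, 3.5, 15.75),
        n_replicates: int = 3,
    ) -> "ExperimentDesign":
        return cls(
            initial_cells=initial_cells,
            moi=moi,
            n_replicates=n_replicates,
            sample_times_h=tuple(sample_times_h),
        )

    @classmethod
    def community(
        cls,
        hosts=("CBA 38", "CBA 4", "CBA 18", "PSA H100", "PSA 13-15"),
        cells_per_strain: float = 2e6,
        moi: float = 0.1,
        sampling_interval_h: float = 35.0 / 60.0,
        duration_h: float = 15.75,
        n_replicates: int = 3,
        moi_convention: str = "flask",
    ) -> "ExperimentDesign":
        return cls(
            initial_cells={h: cells_per_strain for h in hosts},
            moi=moi,
            sampling_interval_h=sampling_interval_h,
            duration_h=duration_h,
            n_replicates=n_replicates,
            moi_convention=moi_convention,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise with left-censoring.

    ``sigma_obs`` is the SD of additive Gaussian noise on log10 densities;
    observations falling below ``detection_floor`` are recorded at the floor
    with ``below_detection = True``.
    """

    sigma_obs: float = 0.15
    detection_floor: float = 1e2

    def __post_init__(self):
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection floor must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator):
        values = np.asarray(values, dtype=float)
        if self.sigma_obs > 0:
            noisy = values * 10 ** (self.sigma_obs * rng.standard_normal(values.shape))
        else:
            noisy = values.copy()
        censored = noisy < self.detection_floor
        noisy = np.where(censored, self.detection_floor, noisy)
        return noisy, censored


def initial_conditions_from_moi(
    cells: Mapping[str, float],
    moi: float,
    matrix: InfectionMatrix,
    convention: str = "flask",
) -> tuple:
    """Initial (host, phage) densities from per-strain cells and an MOI.

    ``flask``: total added phage equals ``moi`` times total cells, split
    equally across phage strains (the study's printed totals: 2x10^8 phage
    over 2x10^9 cells at MOI 0.1, i.e. 4x10^7 per phage strain).
    ``per_phage``: each phage strain individually at ``moi`` x total cells.
    """
    if moi < 0:
        raise ValueError("MOI must be >= 0")
    s0 = {h: float(cells[h]) for h in matrix.hosts}
    total = sum(s0.values())
    if convention == "flask":
        v_each = moi * total / len(matrix.phages)
    elif convention == "per_phage":
        v_each = moi * total
    else:
        raise ValueError("convention must be 'flask' or 'per_phage'")
    v0 = {p: v_each for p in matrix.phages}
    return s0, v0


# ---------------------------------------------------------------------------
# tidy dataset container
# ---------------------------------------------------------------------------


class TimeSeriesDataset:
    """Replicated observed densities in tidy form, plus a provenance manifest.

    Columns: ``time_h, id, replicate, observable, value, below_detection``.
    """

    def __init__(self, frame: pd.DataFrame, manifest: dict | None = None):
        missing = [c for c in SCHEMA if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns: {missing}")
        if (frame["value"] < 0).any():
            raise ValueError("densities must be >= 0")
        dup = frame.duplicated(subset=["time_h", "id", "replicate", "observable"])
        if dup.any():
            rows = frame.index[dup].tolist()[:5]
            raise ValueError(f"duplicate (time, id, replicate, observable) keys at rows {rows}")
        self.frame = frame.reset_index(drop=True)[SCHEMA]
        self.manifest = manifest or {}
        self._series_cache: dict | None = None

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, TimeSeriesDataset) and self.frame.equals(other.frame)

    def ids(self) -> list:
        return sorted(self.frame["id"].unique())

    def observables(self) -> list:
        return sorted(self.frame["observable"].unique())

    def n_replicates(self) -> int:
        return int(self.frame["replicate"].nunique())

    def replicates(self) -> list:
        return sorted(self.frame["replicate"].unique())

    def times(self, ident: str, observable: str) -> np.ndarray:
        sel = self.frame[(self.frame["id"] == ident) & (self.frame["observable"] == observable)]
        return np.sort(sel["time_h"].unique())

    def series(self) -> dict:
        """{(id, observable): (times, values[n_rep, n_t])}; censored -> NaN.

        Cached: the frame is treated as immutable after construction.
        """
        if self._series_cache is not None:
            return self._series_cache
        out = {}
        for (ident, obs), grp in self.frame.groupby(["id", "observable"], sort=True):
            piv = grp.pivot(index="replicate", columns="time_h", values="value").sort_index()
            cen = grp.pivot(index="replicate", columns="time_h", values="below_detection").sort_index()
            vals = piv.to_numpy(dtype=float)
            vals[cen.to_numpy(dtype=bool)] = np.nan
            out[(ident, obs)] = (piv.columns.to_numpy(dtype=float), vals)
        self._series_cache = out
        return out

    def select_replicates(self, reps) -> "TimeSeriesDataset":
        keep = [self.replicates()[r] if isinstance(r, int) else r for r in reps]
        return TimeSeriesDataset(
            self.frame[self.frame["replicate"].isin(keep)].copy(), dict(self.manifest)
        )

    def drop_replicates(self, reps) -> "TimeSeriesDataset":
        drop = [self.replicates()[r] if isinstance(r, int) else r for r in reps]
        return TimeSeriesDataset(
            self.frame[~self.frame["replicate"].isin(drop)].copy(), dict(self.manifest)
        )

    def truncate(self, t_max_h: float) -> "TimeSeriesDataset":
        return TimeSeriesDataset(
            self.frame[self.frame["time_h"] <= t_max_h + 1e-9].copy(), dict(self.manifest)
        )


def _emit(records, times, ident, rep, observable, values, censored):
    for t, v, c in zip(times, values, censored):
        records.append((float(t), ident, int(rep), observable, float(v), bool(c)))


def _traits_dict(ts: TraitSet) -> dict:
    return {
        "r": ts.r,
        "phi": ts.phi,
        "tau": ts.tau,
        "n_exposed": ts.n_exposed,
        "burst_size": ts.burst_size,
        "debris_halfsat": None if math.isinf(ts.debris_halfsat) else ts.debris_halfsat,
        "hill_coeff": ts.hill_coeff,
    }


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_onestep_protocol(
    traits: TraitSet,
    design: ExperimentDesign,
    times: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-2,
):
    """Noise-free one-step trajectory: adsorption phase, dilution, sampling.

    Returns ``(times, free_phage, total_phage)`` with times measured from the
    moment phage and cells are mixed.
    """
    times = design.times() if times is None else np.asarray(times, dtype=float)
    t_dil = design.adsorption_phase_h
    if times.min() < t_dil - 1e-9:
        raise ValueError("one-step samples must follow the adsorption/dilution phase")
    if design.dilutions and design.dilutions[0][0] > times.max():
        raise ValueError("dilution time lies beyond the sampling duration")
    y0 = np.zeros(traits.n_exposed + 4)
    y0[0] = design.total_cells
    y0[2 + traits.n_exposed] = design.initial_phage
    pre = integrate_pairwise_state(traits, y0, np.array([0.0, t_dil]), rtol=rtol, atol=atol)
    y_dil = pre.y[-1] * design.dilution_factor
    grid = np.concatenate([[0.0], times - t_dil]) if times[0] > t_dil else times - t_dil
    traj = integrate_pairwise_state(traits, y_dil, grid, rtol=rtol, atol=atol)
    skip = len(grid) - len(times)
    free = observe(traj, "free_phage")[skip:]
    total = observe(traj, "total_phage")[skip:]
    return times, free, total


def generate_onestep(
    traits: TraitSet,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    phage_id: str = "phage",
) -> TimeSeriesDataset:
    """Synthetic one-step growth dataset (PFU_free and PFU_total)."""
    design = design or ExperimentDesign.onestep()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times, free, total = simulate_onestep_protocol(traits, design)
    records = []
    for rep in range(design.n_replicates):
        fr, fc = noise.apply(free, rng)
        tt, tc = noise.apply(total, rng)
        _emit(records, times, phage_id, rep, "PFU_free", fr, fc)
        _emit(records, times, phage_id, rep, "PFU_total", tt, tc)
    frame = pd.DataFrame(records, columns=SCHEMA)
    manifest = {
        "scenario": "onestep",
        "phage_id": phage_id,
        "seed": seed,
        "noise": {"sigma_obs": noise.sigma_obs, "detection_floor": noise.detection_floor},
        "truth": _traits_dict(traits),
        "design": {
            "initial_cells": design.total_cells,
            "moi": design.moi,
            "adsorption_phase_h": design.adsorption_phase_h,
            "dilution_factor": design.dilution_factor,
            "n_replicates": design.n_replicates,
        },
    }
    return TimeSeriesDataset(frame, manifest)


def generate_pairwise_multicycle(
    traits: TraitSet,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    host_id: str = "host",
    phage_id: str = "phage",
    include_controls: bool = True,
) -> TimeSeriesDataset:
    """Synthetic pairwise multi-cycle infection dataset (qINT/qEXT).

    Controls (phage-free) are emitted as ``<host_id>:control`` qINT series.
    SEIV vs SEIVD mode follows ``traits.debris_halfsat``.
    """
    design = design or ExperimentDesign.pairwise_multicycle()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = design.times()
    s0 = design.total_cells
    v0 = design.initial_phage
    traj = simulate_pairwise(traits, s0, v0, times)
    q_int = observe(traj, "host_qINT")
    q_ext = observe(traj, "phage_qEXT")
    records = []
    for rep in range(design.n_replicates):
        vi, ci = noise.apply(q_int, rng)
        ve, ce = noise.apply(q_ext, rng)
        _emit(records, times, host_id, rep, "qINT", vi, ci)
        _emit(records, times, phage_id, rep, "qEXT", ve, ce)
    if include_controls:
        ctrl = simulate_pairwise(traits, s0, 0.0, times)
        q_ctrl = observe(ctrl, "host_qINT")
        for rep in range(design.n_replicates):
            vc, cc = noise.apply(q_ctrl, rng)
            _emit(records, times, f"{host_id}:control", rep, "qINT", vc, cc)
    frame = pd.DataFrame(records, columns=SCHEMA)
    manifest = {
        "scenario": "pairwise_multicycle",
        "host_id": host_id,
        "phage_id": phage_id,
        "seed": seed,
        "noise": {"sigma_obs": noise.sigma_obs, "detection_floor": noise.detection_floor},
        "truth": _traits_dict(traits),
        "design": {
            "initial_cells": s0,
            "moi": design.moi,
            "sample_times_h": [float(t) for t in times],
            "n_replicates": design.n_replicates,
        },
    }
    return TimeSeriesDataset(frame, manifest)


def generate_community(
    traits: Mapping[tuple, TraitSet],
    matrix: InfectionMatrix,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    attenuation: bool = True,
) -> TimeSeriesDataset:
    """Synthetic community dataset: per-host qINT and per-phage qEXT series."""
    design = design or ExperimentDesign.community(hosts=matrix.hosts)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = design.times()
    cells = design.initial_cells
    if not isinstance(cells, Mapping):
        cells = {h: float(cells) for h in matrix.hosts}
    s0, v0 = initial_conditions_from_moi(cells, design.moi, matrix, design.moi_convention)
    model = CommunityModel(matrix, traits, attenuation=attenuation)
    traj = simulate_community(model, s0, v0, times)
    records = []
    for rep in range(design.n_replicates):
        for h in matrix.hosts:
            vals, cen = noise.apply(observe(traj, "host_qINT", h), rng)
            _emit(records, times, h, rep, "qINT", vals, cen)
        for p in matrix.phages:
            vals, cen = noise.apply(observe(traj, "phage_qEXT", p), rng)
            _emit(records, times, p, rep, "qEXT", vals, cen)
    frame = pd.DataFrame(records, columns=SCHEMA)
    manifest = {
        "scenario": "community",
        "hosts": list(matrix.hosts),
        "phages": list(matrix.phages),
        "seed": seed,
        "attenuation": attenuation,
        "noise": {"sigma_obs": noise.sigma_obs, "detection_floor": noise.detection_floor},
        "truth": {f"{h}|{p}": _traits_dict(ts) for (h, p), ts in traits.items()},
        "design": {
            "cells": {h: float(v) for h, v in cells.items()},
            "moi": design.moi,
            "moi_convention": design.moi_convention,
            "sampling_interval_h": design.sampling_interval_h,
            "duration_h": design.duration_h,
            "n_replicates": design.n_replicates,
        },
    }
    return TimeSeriesDataset(frame, manifest)


def scenario_traitshift(
    traits: Mapping[tuple, TraitSet],
    shifts: Mapping[tuple, Mapping[str, float]],
) -> dict:
    """Community-context trait table with multiplicative shifts applied.

    ``shifts`` maps (host, phage) -> {trait_field: factor}; unnamed pairs and
    fields are returned unchanged.  Models higher-order interactions where a
    trait (e.g. burst size) differs between pairwise and community contexts.
    """
    out = dict(traits)
    for pair, fields in shifts.items():
        if pair not in out:
            raise KeyError(f"unknown pair {pair!r} in shift specification")
        ts = out[pair]
        updates = {}
        for name, factor in fields.items():
            cur = getattr(ts, name)
            updates[name] = type(cur)(cur * factor) if not isinstance(cur, int) else int(round(cur * factor))
        out[pair] = replace(ts, **updates)
    return out
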