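"""File formats and the reproducible pipeline driver.

Plain-text conventions throughout: hours for time, per-ml densities,
comma-separated UTF-8 CSV.  Time-series files use the tidy schema
``time_h, id, replicate, observable, value, below_detection``; infection
matrices are 0/1 CSV with hosts as rows and phage as columns; trait tables
are keyed by ``host_id, phage_id``.  Every run directory gets a JSON
manifest recording the configuration, seed and input-file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models import InfectionMatrix, TraitSet
from .synthetic import SCHEMA, TimeSeriesDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_infection_matrix",
    "write_infection_matrix",
    "read_trait_table",
    "write_trait_table",
    "file_sha256",
    "run_pipeline",
]

TRAIT_COLUMNS = ["host_id", "phage_id", "r", "phi", "tau", "n_exposed", "burst_size", "debris_halfsat", "hill_coeff"]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def read_timeseries(path) -> TimeSeriesDataset:
    """Read a tidy time-series CSV, validating schema, values and key uniqueness.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers.  A JSON manifest sitting next to the CSV (same stem, ``.json``)
    is attached when present.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in SCHEMA[:5] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "below_detection" not in frame.columns:
        frame["below_detection"] = False
    bad = frame.index[~np.isfinite(pd.to_numeric(frame["value"], errors="coerce"))].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]
        raise ValueError(f"{path}: non-numeric values at lines {lines}")
    neg = frame.index[frame["value"] < 0].tolist()
    if neg:
        raise ValueError(f"{path}: negative densities at lines {[i + 2 for i in neg[:10]]}")
    dup = frame.duplicated(subset=["time_h", "id", "replicate", "observable"], keep=False)
    if dup.any():
        lines = [i + 2 for i in frame.index[dup].tolist()[:10]]
        raise ValueError(f"{path}: duplicate (time, id, replicate, observable) keys at lines {lines}")
    frame["below_detection"] = frame["below_detection"].astype(bool)
    manifest = {}
    mpath = path.with_suffix(".json")
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return TimeSeriesDataset(frame, manifest)


def write_timeseries(dataset: TimeSeriesDataset, path, write_manifest: bool = True) -> Path:
    """Write the tidy CSV (plus a sidecar JSON manifest). Round-trips losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.frame.to_csv(path, index=False)
    if write_manifest and dataset.manifest:
        path.with_suffix(".json").write_text(json.dumps(dataset.manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# infection matrix and trait tables
# ---------------------------------------------------------------------------


def read_infection_matrix(path, expect_shape: tuple | None = None) -> InfectionMatrix:
    """Read a 0/1 CSV host-range matrix (hosts as rows, phage as columns)."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    ok = np.isin(values, (0, 1))
    if not ok.all():
        bad = sorted(set(np.asarray(values)[~ok].tolist()))
        raise ValueError(f"{path}: infection matrix entries must be 0/1, found {bad}")
    if expect_shape is not None and values.shape != tuple(expect_shape):
        raise ValueError(
            f"{path}: expected {expect_shape[0]} hosts x {expect_shape[1]} phages, "
            f"got {values.shape} (transposed file?)"
        )
    return InfectionMatrix(
        hosts=tuple(str(h) for h in frame.index),
        phages=tuple(str(p) for p in frame.columns),
        mask=values.astype(bool),
    )


def write_infection_matrix(matrix: InfectionMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(matrix.mask.astype(int), index=list(matrix.hosts), columns=list(matrix.phages))
    frame.to_csv(path)
    return path


def read_trait_table(path) -> dict:
    """Read a per-pair trait table CSV into ``{(host, phage): TraitSet}``.

    An empty/missing ``debris_halfsat`` means no attenuation (D_c = inf).
    """
    frame = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS[:7] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: trait table is missing columns {missing}")
    out = {}
    for _, row in frame.iterrows():
        dc = row.get("debris_halfsat", math.nan)
        dc = math.inf if pd.isna(dc) else float(dc)
        hill = row.get("hill_coeff", 2.0)
        hill = 2.0 if pd.isna(hill) else float(hill)
        out[(str(row["host_id"]), str(row["phage_id"]))] = TraitSet(
            r=float(row["r"]),
            phi=float(row["phi"]),
            tau=float(row["tau"]),
            n_exposed=int(row["n_exposed"]),
            burst_size=float(row["burst_size"]),
            debris_halfsat=dc,
            hill_coeff=hill,
        )
    return out


def write_trait_table(traits: Mapping[tuple, TraitSet], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for (h, p), ts in traits.items():
        rows.append(
            {
                "host_id": h,
                "phage_id": p,
                "r": ts.r,
                "phi": ts.phi,
                "tau": ts.tau,
                "n_exposed": ts.n_exposed,
                "burst_size": ts.burst_size,
                "debris_halfsat": "" if math.isinf(ts.debris_halfsat) else ts.debris_halfsat,
                "hill_coeff": ts.hill_coeff,
            }
        )
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _write_posterior(ensemble, out_dir: Path, tag: str) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    post_csv = out_dir / f"{tag}_posterior.csv"
    ensemble.draws.to_csv(post_csv, index=False)
    summary = ensemble.summary()
    summary_json = out_dir / f"{tag}_summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"posterior_csv": str(post_csv), "summary_json": str(summary_json)}


def run_pipeline(config: Mapping, out_dir) -> dict:
    """Run a configured generate -> fit -> compare workflow; returns the bundle.

    The demo configuration generates a synthetic one-step dataset and a small
    community dataset from stated ground-truth traits, runs the pairwise and
    community Bayesian fits, compares shared traits, and writes a
    self-describing result bundle (posterior CSVs, summary JSONs with R-hat
    and acceptance rates, equivalence JSON, log, config echo with hashes).
    Outputs are reproducible byte-for-byte given (config, seed).
    """
    from .inference import (
        SamplerSettings,
        equivalence_test,
        fit_community,
        fit_pairwise_onestep,
    )
    from .models import default_community_matrix
    from .synthetic import ExperimentDesign, NoiseModel, generate_community, generate_onestep

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    steps = int(config.get("n_steps", 800))
    sigma = float(config.get("sigma_obs", 0.1))
    bundle: dict = {"config": dict(config), "seed": seed}

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("seivd")
    root.addHandler(handler)
    try:
        root.info("pipeline start: seed=%d steps=%d sigma=%g", seed, steps, sigma)
        truth = TraitSet(
            r=math.log(2) / 4,
            phi=1e-7,
            tau=1.0,
            n_exposed=int(config.get("n_exposed", 24)),
            burst_size=50.0,
        )
        design = ExperimentDesign.onestep(n_replicates=3)
        noise = NoiseModel(sigma_obs=sigma)
        data = generate_onestep(truth, design, noise, seed=seed)
        ds_path = write_timeseries(data, out_dir / "onestep_data.csv")
        bundle["onestep_data"] = str(ds_path)
        root.info("onestep data sha256=%s", file_sha256(ds_path))

        ens_pair = fit_pairwise_onestep(
            data,
            design,
            r=truth.r,
            sigma=sigma,
            settings=SamplerSettings(n_steps=steps),
            seed=seed,
        )
        bundle["pairwise_fit"] = _write_posterior(ens_pair, out_dir, "pairwise")
        root.info("pairwise fit acceptance=%.3f", ens_pair.acceptance_rate)

        matrix = config.get("matrix") or default_community_matrix()
        sub_hosts = tuple(matrix.hosts[:2])
        sub_phages = tuple(matrix.phages[:2])
        sub_mask = np.ones((2, 2), dtype=bool)
        sub = InfectionMatrix(sub_hosts, sub_phages, sub_mask)
        comm_truth = {
            (h, p): truth.with_(n_exposed=4, debris_halfsat=1e6)
            for h in sub_hosts
            for p in sub_phages
        }
        cdesign = ExperimentDesign.community(hosts=sub_hosts, sampling_interval_h=35.0 / 60.0)
        cdata = generate_community(comm_truth, sub, cdesign, NoiseModel(sigma_obs=sigma), seed=seed + 1)
        cd_path = write_timeseries(cdata, out_dir / "community_data.csv")
        bundle["community_data"] = str(cd_path)

        cells = {h: 2e6 for h in sub_hosts}
        from .synthetic import initial_conditions_from_moi

        s0, v0 = initial_conditions_from_moi(cells, 0.1, sub)
        ens_comm = fit_community(
            cdata,
            sub,
            host_r={h: truth.r for h in sub_hosts},
            s0=s0,
            v0=v0,
            n_exposed=4,
            sigma=sigma,
            settings=SamplerSettings(n_steps=steps),
            seed=seed + 2,
        )
        bundle["community_fit"] = _write_posterior(ens_comm, out_dir, "community")

        comparisons = {}
        pair_key = f"{sub_hosts[0]}|{sub_phages[0]}"
        for trait, comm_name in (("phi", f"phi:{pair_key}"), ("tau", f"tau:{pair_key}"), ("beta", f"beta:{pair_key}")):
            res = equivalence_test(
                ens_pair.draws[trait].to_numpy(),
                ens_comm.draws[comm_name].to_numpy(),
                rope_halfwidth=float(config.get("rope", 0.1)),
                trait=trait,
            )
            comparisons[trait] = {
                "p_eq": res.p_eq,
                "verdict": res.verdict,
                "delta_median_log10": res.delta_median,
            }
        eq_path = out_dir / "equivalence.json"
        eq_path.write_text(json.dumps(comparisons, indent=2, sort_keys=True))
        bundle["equivalence_json"] = str(eq_path)

        bundle["log"] = str(log_path)
        cfg_path = out_dir / "run_config.json"
        serialisable = {k: v for k, v in bundle["config"].items() if isinstance(v, (int, float, str, bool, type(None)))}
        cfg_path.write_text(json.dumps({"config": serialisable, "seed": seed}, indent=2, sort_keys=True))
        bundle["config_json"] = str(cfg_path)
        root.info("pipeline complete")
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle
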