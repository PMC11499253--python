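"""File formats, session bundles and pipeline orchestration.

Rasters travel as HDF5/NPZ/CSV (neurons x frames with a frame-rate
attribute), bout tables as CSV with columns actor, behavior, start_frame,
stop_frame.  ``run_pipeline`` chains the stages (simulate -> single-cell
metrics -> rSLDS -> integrator -> decoder) and records a manifest of seeds,
stage status and wall times, so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BoutTable
from .containers import PopulationRaster, zscore_rows

__all__ = ["RunManifest", "read_raster", "write_raster", "read_bouts",
           "write_bouts", "save_session", "load_session", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)
    config_hash: str = ""

    def record(self, name: str, status: str, seconds: float,
               detail: str = "") -> None:
        self.stages.append({"stage": name, "status": status,
                            "wall_seconds": round(seconds, 3),
                            "detail": detail})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "config_hash": self.config_hash, "stages": self.stages},
            indent=2, default=str))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def read_raster(path: str | Path, frame_rate: float | None = None,
                zscore: bool = True) -> PopulationRaster:
    """Load a neurons x frames raster from HDF5, NPZ or CSV.

    The frame rate must be present in the file (HDF5 attribute / NPZ key)
    or passed explicitly.  All-NaN or partially-NaN rows are dropped with a
    warning; if the data are not already z-scored they are z-scored (and
    the caller warned) unless ``zscore=False``.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["raster"][()]
            fr = f["raster"].attrs.get("frame_rate", frame_rate)
    elif path.suffix == ".npz":
        z = np.load(path)
        data = z["raster"]
        fr = float(z["frame_rate"]) if "frame_rate" in z else frame_rate
    elif path.suffix == ".csv":
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
        fr = frame_rate
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    if fr is None:
        raise ValueError("frame rate missing: pass frame_rate=")
    data = np.asarray(data, dtype=float)
    bad = np.isnan(data).any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {bad.sum()} NaN neuron row(s)")
        data = data[~bad]
    mu = np.abs(data.mean(axis=1)).max() if data.size else 0.0
    sd_dev = np.abs(data.std(axis=1) - 1).max() if data.size else 0.0
    if zscore and (mu > 1e-6 or sd_dev > 1e-6):
        warnings.warn("raster not z-scored; applying per-neuron z-scoring")
        data, const = zscore_rows(data)
        if const.any():
            warnings.warn(f"{const.sum()} constant neuron row(s) left unscaled")
    return PopulationRaster(data, frame_rate=float(fr))


def write_raster(raster: PopulationRaster, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("raster", data=raster.data)
            ds.attrs["frame_rate"] = raster.frame_rate
    elif path.suffix == ".npz":
        np.savez(path, raster=raster.data, frame_rate=raster.frame_rate)
    elif path.suffix == ".csv":
        pd.DataFrame(raster.data).to_csv(path, header=False, index=False)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")


def read_bouts(path: str | Path, frame_rate: float = 10.0) -> BoutTable:
    """Read a bout table CSV (actor, behavior, start_frame, stop_frame).

    Rejects malformed rows and overlapping same-label bouts, naming the
    offending row numbers.
    """
    df = pd.read_csv(path)
    required = ["actor", "behavior", "start_frame", "stop_frame"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"bout CSV missing columns {missing}")
    bad = df.index[(~np.isfinite(df["start_frame"])) |
                   (~np.isfinite(df["stop_frame"])) |
                   (df["start_frame"] >= df["stop_frame"])].tolist()
    if bad:
        raise ValueError(f"malformed bout rows (start >= stop or non-finite): "
                         f"{[i + 2 for i in bad]}")  # +2: header + 0-base
    table = df.rename(columns={"start_frame": "start", "stop_frame": "stop"})
    try:
        return BoutTable(table, frame_rate=frame_rate)
    except ValueError as err:
        raise ValueError(f"invalid bout table in {path}: {err}") from err


def write_bouts(bouts: BoutTable, path: str | Path) -> None:
    out = bouts.df.rename(columns={"start": "start_frame",
                                   "stop": "stop_frame"})
    out.to_csv(path, index=False)


def save_session(session, path: str | Path) -> None:
    """Write a synthetic session as an HDF5 bundle plus CSV bout tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "session.h5", "w") as f:
        ds = f.create_dataset("raster", data=session.raster.data)
        ds.attrs["frame_rate"] = session.raster.frame_rate
        f.create_dataset("latents", data=session.latents.x)
        for key, val in session.true_params.items():
            f.create_dataset(f"true_params/{key}", data=np.asarray(val))
    write_bouts(session.male_bouts, path / "male_bouts.csv")
    write_bouts(session.female_bouts, path / "female_bouts.csv")


def load_session(path: str | Path) -> dict:
    path = Path(path)
    with h5py.File(path / "session.h5", "r") as f:
        raster = PopulationRaster(f["raster"][()],
                                  frame_rate=float(f["raster"].attrs["frame_rate"]))
        latents = f["latents"][()]
        true_params = {k: f[f"true_params/{k}"][()] for k in f["true_params"]}
    fr = raster.frame_rate
    return {"raster": raster, "latents": latents, "true_params": true_params,
            "male_bouts": read_bouts(path / "male_bouts.csv", fr),
            "female_bouts": read_bouts(path / "female_bouts.csv", fr)}


def run_pipeline(config: dict, out_dir: str | Path | None = None
                 ) -> tuple[RunManifest, dict]:
    """Run the synthetic end-to-end analysis described by ``config``.

    Stages (each individually switchable via ``config['stages']``):
    simulate, metrics (ACHW), rslds (fit + time constants + score),
    integrator, decode.  A stage failure is recorded and dependent stages
    are skipped.  Returns the manifest and a dict of in-memory results.
    """
    from . import rslds as R
    from . import single_cell as SC
    from .integrator import fit_input_driven_integrator
    from .synthetic import SimConfig, simulate_session

    seed = int(config.get("seed", 0))
    stages = config.get("stages",
                        ["simulate", "metrics", "rslds", "integrator",
                         "decode"])
    manifest = RunManifest(config=config, seed=seed,
                           config_hash=_config_hash(config))
    results: dict = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn, requires=()):
        if name not in stages:
            return
        for req in requires:
            if req in stages and req not in results:
                manifest.record(name, "skipped", 0.0,
                                f"dependency {req} unavailable")
                return
        t0 = time.time()
        try:
            results[name] = fn()
            manifest.record(name, "ok", time.time() - t0)
        except Exception as err:  # noqa: BLE001 - recorded, not silenced
            manifest.record(name, "failed", time.time() - t0, repr(err))

    def _simulate():
        sim_cfg = SimConfig(seed=seed, **config.get("sim", {}))
        session = simulate_session(sim_cfg)
        if out_dir is not None:
            save_session(session, out_dir / "session")
        return session

    def _metrics():
        sess = results["simulate"]
        achw = [SC.autocorr_halfwidth(tr, sess.raster.frame_rate).achw_seconds
                for tr in sess.raster.data]
        return {"achw_seconds": np.array(achw)}

    def _rslds():
        sess = results["simulate"]
        params, lat, diag = R.fit_rslds(
            sess.raster, K=config.get("K", 1), D=config.get("D", 2),
            config=R.FitConfig(seed=seed))
        tcs = R.time_constants(params, sess.raster.frame_rate, lat)
        return {"params": params, "latents": lat, "diagnostics": diag,
                "time_constants": tcs,
                "line_attractor_score": R.line_attractor_score(tcs),
                "integration": R.integration_dimension(params, lat)}

    def _integrator():
        sess = results["simulate"]
        series = results["rslds"]["integration"]["raw_series"]
        return fit_input_driven_integrator(series, sess.male_bouts,
                                           frame_rate=sess.raster.frame_rate)

    def _decode():
        sess = results["simulate"]
        cop = sess.male_bouts.select(actor="male", group="copulation")
        sniff = sess.male_bouts.select(actor="male", group="sniff")
        if len(cop) == 0 or len(sniff) == 0:
            raise ValueError("not enough bouts to decode")
        return SC.framewise_svm_decoder(sess.raster, cop, sniff, seed=seed)

    run_stage("simulate", _simulate)
    run_stage("metrics", _metrics, requires=("simulate",))
    run_stage("rslds", _rslds, requires=("simulate",))
    run_stage("integrator", _integrator, requires=("simulate", "rslds"))
    run_stage("decode", _decode, requires=("simulate",))
    if out_dir is not None:
        manifest.to_json(out_dir / "manifest.json")
    return manifest, results
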