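"""Trace and event I/O plus the declarative pipeline runner.

Trace containers:

* raw little-endian float32 (``.bin``/``.raw``/``.dat``) with a JSON sidecar
  (``<file>.json``) carrying at least the sampling rate;
* CSV with a ``current`` column and either an ``fs`` passed explicitly or a
  ``time`` column from which fs is inferred;
* NumPy ``.npy``;
* HDF5 (``.h5``/``.hdf5``) with dataset ``current`` and attribute ``fs``.

Event tables are written as CSV or JSON lines. :func:`run_pipeline` executes
a YAML-described analysis (simulate/detect/estimate/classify) end to end and
stamps every output with the config hash and seeds for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .detector import EventRecord, TSWConfig, TSWDetector

_RAW_SUFFIXES = {".bin", ".raw", ".dat"}


def write_trace(path: str, trace: np.ndarray, fs: float, meta: Optional[dict] = None) -> None:
    """Write a trace in the format implied by the file suffix."""
    p = Path(path)
    trace = np.asarray(trace, dtype=np.float64)
    if fs <= 0:
        raise ValueError("fs must be positive")
    suffix = p.suffix.lower()
    if suffix in _RAW_SUFFIXES:
        trace.astype("<f4").tofile(p)
        sidecar = {"fs": fs, "dtype": "<f4", "n_samples": int(trace.size)}
        if meta:
            sidecar.update(meta)
        Path(str(p) + ".json").write_text(json.dumps(sidecar, indent=2))
    elif suffix == ".csv":
        import pandas as pd

        t = np.arange(trace.size) / fs
        pd.DataFrame({"time": t, "current": trace}).to_csv(p, index=False)
    elif suffix == ".npy":
        np.save(p, trace)
        Path(str(p) + ".json").write_text(json.dumps({"fs": fs}))
    elif suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(p, "w") as f:
            d = f.create_dataset("current", data=trace.astype(np.float32))
            d.attrs["fs"] = fs
            if meta:
                for k, v in meta.items():
                    try:
                        d.attrs[k] = v
                    except TypeError:
                        d.attrs[k] = json.dumps(v)
    else:
        raise ValueError(f"unsupported trace format: {suffix!r}")


def read_trace(path: str, fs: Optional[float] = None) -> Tuple[np.ndarray, float]:
    """Read a trace; returns (samples, fs). ``fs`` overrides any stored rate."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    suffix = p.suffix.lower()
    if suffix in _RAW_SUFFIXES:
        sidecar = Path(str(p) + ".json")
        stored = None
        dtype = "<f4"
        if sidecar.exists():
            obj = json.loads(sidecar.read_text())
            stored = obj.get("fs")
            dtype = obj.get("dtype", "<f4")
        rate = fs if fs is not None else stored
        if rate is None:
            raise ValueError(
                "raw trace needs a sampling rate: pass fs or provide a JSON sidecar"
            )
        data = np.fromfile(p, dtype=dtype).astype(np.float64)
        return data, float(rate)
    if suffix == ".csv":
        import pandas as pd

        df = pd.read_csv(p)
        cols = {c.lower(): c for c in df.columns}
        if "current" not in cols:
            raise ValueError("CSV trace needs a 'current' column")
        data = df[cols["current"]].to_numpy(dtype=np.float64)
        if fs is not None:
            return data, float(fs)
        if "time" in cols:
            t = df[cols["time"]].to_numpy(dtype=np.float64)
            if t.size < 2:
                raise ValueError("cannot infer fs from a single time sample")
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time column must be strictly increasing")
            return data, float(1.0 / np.median(dt))
        raise ValueError("CSV trace needs a 'time' column or an explicit fs")
    if suffix == ".npy":
        data = np.load(p).astype(np.float64)
        if fs is not None:
            return data, float(fs)
        sidecar = Path(str(p) + ".json")
        if sidecar.exists():
            return data, float(json.loads(sidecar.read_text())["fs"])
        raise ValueError("npy trace needs an explicit fs or a JSON sidecar")
    if suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(p, "r") as f:
            if "current" not in f:
                raise ValueError("HDF5 trace needs a 'current' dataset")
            d = f["current"]
            data = d[...].astype(np.float64)
            rate = fs if fs is not None else d.attrs.get("fs")
        if rate is None:
            raise ValueError("HDF5 trace needs an 'fs' attribute or explicit fs")
        return data, float(rate)
    raise ValueError(f"unsupported trace format: {suffix!r}")


# -- event tables -----------------------------------------------------------

_EVENT_FIELDS = [
    "start_index",
    "end_index",
    "dwell_s",
    "baseline_pA",
    "sigma_pA",
    "delta_i_mean",
    "i_min",
    "i_max",
    "clog",
]


def write_events(path: str, events: Sequence[EventRecord], extra: Optional[Sequence[dict]] = None) -> None:
    """Write events as CSV (``.csv``) or JSON lines (``.jsonl``/``.json``).

    ``extra`` optionally supplies one dict per event of additional columns
    (e.g. shape estimates or class labels)."""
    p = Path(path)
    rows = []
    for i, ev in enumerate(events):
        row = {k: getattr(ev, k) for k in _EVENT_FIELDS}
        if extra is not None:
            row.update(extra[i])
        rows.append(row)
    if p.suffix.lower() == ".csv":
        import pandas as pd

        pd.DataFrame(rows).to_csv(p, index=False)
    elif p.suffix.lower() in {".jsonl", ".json"}:
        with open(p, "w") as f:
            for row in rows:
                f.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unsupported event format: {p.suffix!r}")


def read_events(path: str) -> List[dict]:
    p = Path(path)
    if p.suffix.lower() == ".csv":
        import pandas as pd

        return pd.read_csv(p).to_dict(orient="records")
    if p.suffix.lower() in {".jsonl", ".json"}:
        return [json.loads(line) for line in p.read_text().splitlines() if line.strip()]
    raise ValueError(f"unsupported event format: {p.suffix!r}")


# -- chunked streaming ------------------------------------------------------

def iter_chunks(trace: np.ndarray, chunk_size: int) -> Iterator[np.ndarray]:
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    for i in range(0, trace.size, chunk_size):
        yield trace[i : i + chunk_size]


def stream_loop(
    chunks: Iterable[np.ndarray],
    detector: TSWDetector,
    log=None,
) -> List[EventRecord]:
    """Feed chunks through the detector, optionally logging per-chunk timing.

    ``log`` is a callable receiving one line per chunk:
    ``chunk=<i> samples=<n> events=<k> wall_ms=<t> throughput_MSps=<r>``.
    """
    events: List[EventRecord] = []
    for i, chunk in enumerate(chunks):
        t0 = time.perf_counter()
        got = detector.process(np.asarray(chunk, dtype=np.float64))
        dt = time.perf_counter() - t0
        events.extend(got)
        if log is not None:
            rate = (len(chunk) / dt / 1e6) if dt > 0 else float("inf")
            log(
                f"chunk={i} samples={len(chunk)} events={len(got)} "
                f"wall_ms={dt * 1e3:.2f} throughput_MSps={rate:.1f}"
            )
    return events


# -- declarative pipeline ---------------------------------------------------

def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config_path: str, out_dir: Optional[str] = None, log=print) -> dict:
    """Run a YAML-described analysis.

    Sections (each optional, executed in order when present):

    ``simulate``: kwargs for :class:`~nanopulse.simulate.SquarePulseSpec`
    plus ``kind: square|modulated|protein`` (protein takes ``proteins:`` a
    list of ``{m, volume, label}``, ``pore:`` kwargs, and trace kwargs).
    ``trace``: ``{path: ..., fs: ...}`` to read an existing trace instead.
    ``detect``: kwargs for :class:`~nanopulse.detector.TSWConfig` (``fs``
    defaults to the trace rate) plus optional ``chunk_size`` and ``algo:
    tsw|ts``.
    ``estimate``: ``{pore: {...}}`` -- per-event shape fits plus the
    cumulative residence-time-weighted estimate.
    ``classify``: ``{model: path.json}`` or ``{train: {...}}``.
    ``output``: ``{events: path, summary: path}``.

    Returns a summary dict; all outputs carry the config hash and seed.
    """
    import yaml

    cfg_path = Path(config_path)
    cfg = yaml.safe_load(cfg_path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    digest = config_hash(cfg)
    out = Path(out_dir) if out_dir else cfg_path.parent
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    summary: dict = {"config_hash": digest, "seed": seed}

    trace = None
    fs = None
    truth = None
    if "simulate" in cfg:
        from . import simulate as sim

        sc = dict(cfg["simulate"])
        kind = sc.pop("kind", "square")
        if kind in ("square", "modulated"):
            spec = sim.SquarePulseSpec(**{**sc, "seed": sc.get("seed", seed)})
            fn = sim.simulate_modulated_trace if kind == "modulated" else sim.simulate_square_trace
            trace, truth = fn(spec)
            fs = spec.fs
        elif kind == "protein":
            proteins = [sim.ProteinSpec(**p) for p in sc.pop("proteins")]
            pore = sim.PoreSpec(**sc.pop("pore", {}))
            sc.setdefault("seed", seed)
            trace, truth = sim.simulate_protein_trace(proteins, pore, **sc)
            fs = sc.get("fs", 500_000.0)
            summary["pore"] = pore.__dict__
        else:
            raise ValueError(f"unknown simulate kind: {kind!r}")
        summary["n_truth_events"] = len(truth)
    elif "trace" in cfg:
        trace, fs = read_trace(cfg["trace"]["path"], cfg["trace"].get("fs"))
    else:
        raise ValueError("config needs a 'simulate' or 'trace' section")
    summary["fs"] = fs
    summary["n_samples"] = int(trace.size)

    events: List[EventRecord] = []
    if "detect" in cfg:
        dc = dict(cfg["detect"])
        algo = dc.pop("algo", "tsw")
        chunk_size = int(dc.pop("chunk_size", 1_000_000))
        dc.setdefault("fs", fs)
        if algo == "tsw":
            det = TSWDetector(TSWConfig(**dc))
            events = stream_loop(iter_chunks(trace, chunk_size), det, log=log)
        elif algo == "ts":
            from .threshold import TSConfig, ts_detect

            events = ts_detect(trace, TSConfig(**dc))
        else:
            raise ValueError(f"unknown detection algo: {algo!r}")
        summary["n_events"] = len(events)

    extra: Optional[List[dict]] = None
    if "estimate" in cfg and events:
        from .shape import (
            CumulativeEstimate,
            cumulative_update,
            filtered_orientation_quantiles,
            fit_event,
        )
        from .simulate import PoreSpec

        ec = cfg["estimate"]
        pore = PoreSpec(**ec.get("pore", {}))
        oq = None
        if "bandwidth" in ec:
            bw = ec["bandwidth"]
            oq = filtered_orientation_quantiles(
                float(bw.get("rot_diffusion", 16_667.0)),
                float(bw.get("fs", fs)),
                float(bw["fc"]),
            )
        cum = CumulativeEstimate()
        extra = []
        pad = 3
        for ev in events:
            s = np.asarray(ev.samples, dtype=float)
            core = s[pad : s.size - pad] if s.size > 2 * pad else s
            mags = np.abs(core - ev.baseline_pA)
            if mags.size < 10:  # too short to constrain the fit
                extra.append({"m_hat": None, "v_hat_nm3": None, "fit_converged": False})
                continue
            est = fit_event(mags, ev.sigma_pA, pore, ev.baseline_pA,
                            orientation_quantiles=oq)
            cumulative_update(cum, est, ev.dwell_s)
            extra.append(
                {
                    "m_hat": est.m_hat,
                    "v_hat_nm3": est.v_hat,
                    "fit_converged": est.converged,
                }
            )
        summary["cumulative_m"] = cum.m_hat
        summary["cumulative_v_nm3"] = cum.v_hat
        summary["n_pooled_events"] = cum.n_events

    if "classify" in cfg and events:
        from .classify import BlockadeNBC

        cc = cfg["classify"]
        if "model" in cc:
            model = BlockadeNBC.from_json(Path(cc["model"]).read_text())
        else:
            raise ValueError("classify section needs a 'model' path")
        labels = model.predict(events)
        if extra is None:
            extra = [{} for _ in events]
        for row, lab in zip(extra, labels):
            row["label"] = lab
        summary["label_counts"] = {
            lab: int(sum(1 for v in labels if v == lab)) for lab in sorted(set(labels))
        }

    out_cfg = cfg.get("output", {})
    if "events" in out_cfg and events:
        write_events(str(out / out_cfg["events"]), events, extra)
        summary["events_path"] = str(out / out_cfg["events"])
    summary_path = out / out_cfg.get("summary", "summary.json")
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    summary["summary_path"] = str(summary_path)
    return summary
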