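"""File I/O: binding-curve CSVs, model/rate JSON configs, chain tables.

Tabular artifacts are CSV; configurations and fit summaries are JSON.  The
dataset schema is ``time_h, y, variant`` with an optional per-point
``sigma`` column; malformed rows are rejected with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import BindingDataset, ParameterVector, PosteriorSample, param_names
from .schemes import ModelSpec, RateConstants, TimeCourse

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_model_config",
    "write_model_config",
    "write_timecourse",
    "write_chains",
    "read_chains",
    "write_fit_summary",
]

_DATASET_COLUMNS = ("time_h", "y", "variant")


def read_dataset(path: str | Path, sigma: float = 0.05) -> BindingDataset:
    """Read binding curves from CSV (columns ``time_h, y, variant``).

    Raises ``ValueError`` naming any missing column, and listing the CSV
    line numbers of non-numeric or negative-time rows.  Duplicate
    (variant, time) rows are preserved as given.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path}: missing column(s) {', '.join(missing)}")
    # +2: one for the header line, one for 1-based numbering
    lines = df.index.to_numpy() + 2
    bad = []
    for col in ("time_h", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad.extend(lines[vals.isna().to_numpy()].tolist())
        df[col] = vals
    if bad:
        raise ValueError(f"dataset {path}: non-numeric values at line(s) {sorted(set(bad))}")
    neg = lines[(df["time_h"] < 0).to_numpy()]
    if len(neg):
        raise ValueError(f"dataset {path}: negative times at line(s) {neg.tolist()}")
    if "sigma" in df.columns:
        sigma = float(pd.to_numeric(df["sigma"], errors="raise").iloc[0])
    curves = {}
    for variant, sub in df.groupby("variant", sort=True):
        sub = sub.sort_values("time_h", kind="stable")
        curves[str(variant)] = (
            sub["time_h"].to_numpy(dtype=float),
            sub["y"].to_numpy(dtype=float),
        )
    return BindingDataset(curves=curves, sigma=sigma)


def write_dataset(path: str | Path, data: BindingDataset) -> None:
    """Write binding curves as CSV, lossless against :func:`read_dataset`."""
    rows = []
    for variant, (t, y) in sorted(data.curves.items()):
        for ti, yi in zip(t, y):
            rows.append({"time_h": ti, "y": yi, "variant": variant, "sigma": data.sigma})
    pd.DataFrame(rows).to_csv(path, index=False)


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "kind": spec.kind,
        "n": spec.threshold_n,
        "kaib": spec.kaib_present,
        "m": spec.dead_sites_m,
    }


def read_model_config(path: str | Path) -> tuple[ModelSpec, RateConstants]:
    """Read a JSON document ``{"model": {...}, "rates": {...}}``."""
    with open(path) as fh:
        doc = json.load(fh)
    m = doc["model"]
    spec = ModelSpec(
        kind=m.get("kind", "hexamer"),
        threshold_n=int(m.get("n", 6)),
        kaib_present=bool(m.get("kaib", True)),
        dead_sites_m=int(m.get("m", 0)),
    )
    r = doc["rates"]
    rc = RateConstants(
        k_h=float(r["kh"]),
        k_h_star=float(r.get("kh_star", r["kh"])),
        k_e=float(r["ke"]),
        k_e_star=float(r["ke_star"]),
    )
    return spec, rc


def write_model_config(path: str | Path, spec: ModelSpec, rc: RateConstants) -> None:
    doc = {
        "model": _spec_to_dict(spec),
        "rates": {
            "kh": rc.k_h,
            "kh_star": rc.k_h_star,
            "ke": rc.k_e,
            "ke_star": rc.k_e_star,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_timecourse(path: str | Path, tc: TimeCourse, variant: str, model: str) -> None:
    """Write a time course as CSV (time_h, bound_fraction, atpase_per_day, ...)."""
    act = tc.atpase_activity
    pd.DataFrame(
        {
            "time_h": tc.times,
            "bound_fraction": tc.bound_fraction,
            "atpase_per_day": act if act is not None else np.nan,
            "variant": variant,
            "model": model,
        }
    ).to_csv(path, index=False)


def write_chains(path: str | Path, sample: PosteriorSample) -> None:
    """Flattened post-burn-in chains as CSV (walker, step, params..., logpost)."""
    steps, walkers, dim = sample.chain.shape
    rows = []
    for s in range(sample.burn_in, steps, sample.thin):
        for w in range(walkers):
            row = {"walker": w, "step": s}
            row.update(dict(zip(sample.names, sample.chain[s, w])))
            row["logpost"] = sample.log_prob[s, w]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chains(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("walker", "step", "logpost"):
        if col not in df.columns:
            raise ValueError(f"chains {path}: missing column {col}")
    return df


def write_fit_summary(path: str | Path, spec: ModelSpec, sample: PosteriorSample, map_x, map_logpost: float) -> None:
    """JSON summary: MAP, posterior medians and 95% credible intervals."""
    flat = sample.flat_samples
    names = list(sample.names)
    lo, med, hi = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    doc = {
        "model": _spec_to_dict(spec),
        "map": dict(zip(names, map(float, map_x))),
        "map_log_posterior": float(map_logpost),
        "median": dict(zip(names, map(float, med))),
        "ci95_low": dict(zip(names, map(float, lo))),
        "ci95_high": dict(zip(names, map(float, hi))),
        "autocorrelation_time": dict(zip(names, map(float, sample.tau))),
        "burn_in": int(sample.burn_in),
        "thin": int(sample.thin),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
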