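"""Declared on-disk formats and bit-stable round-trip I/O.

Formats:

* discrete trajectories — one integer state per line per file, plus a JSON
  manifest (timestep, model id, seed);
* feature / H-bond tables — CSV with a header row, booleans as 0/1;
* dispersion data — CSV with columns residue, field_mhz, experiment,
  nu_cpmg_hz, omega1_hz, offset_hz, rate_s, error_s;
* kinetic models — YAML; fit and MSM results — JSON.

Readers validate the schema and raise :class:`~dyndesign.errors.SchemaError`
naming the offending field rather than misparsing silently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .designability import HBondTable
from .dispersion import DispersionDataset, TwoStateFit
from .errors import SchemaError
from .synthetic import KineticModel, MacrostateSpec, SyntheticTrajectorySet

_FLOAT_FMT = "%.17g"


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} "
                          f"(line 1, header row)")


# ---------------------------------------------------------------------------
# discrete trajectories
# ---------------------------------------------------------------------------


def write_dtrajs(traj: SyntheticTrajectorySet, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, d in enumerate(traj.dtrajs):
        name = f"dtraj_{i:04d}.txt"
        np.savetxt(outdir / name, d, fmt="%d")
        files.append(name)
    manifest = {"timestep_ns": traj.timestep_ns, "model_ref": traj.model_ref,
                "seed": traj.seed, "files": files}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_dtrajs(manifest_path) -> SyntheticTrajectorySet:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{manifest_path}: invalid JSON manifest "
                          f"({exc})") from exc
    for key in ("timestep_ns", "model_ref", "seed", "files"):
        if key not in manifest:
            raise SchemaError(f"{manifest_path}: missing manifest field "
                              f"{key!r}")
    dtrajs = [np.loadtxt(manifest_path.parent / f, dtype=np.int64, ndmin=1)
              for f in manifest["files"]]
    return SyntheticTrajectorySet(
        dtrajs=dtrajs, features=None, timestep_ns=manifest["timestep_ns"],
        seed=manifest["seed"], model_ref=manifest["model_ref"])


# ---------------------------------------------------------------------------
# feature and H-bond tables
# ---------------------------------------------------------------------------


def write_features_csv(features: list[np.ndarray], path) -> Path:
    rows = []
    for t, f in enumerate(features):
        for i in range(len(f)):
            rows.append((len(rows), t, *f[i]))
    ncol = features[0].shape[1]
    df = pd.DataFrame(rows, columns=["frame", "traj"]
                      + [f"f{j}" for j in range(ncol)])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_features_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "traj"], path)
    fcols = [c for c in df.columns if c.startswith("f") and c != "frame"]
    if not fcols:
        raise SchemaError(f"{path}: no feature columns (f0, f1, ...)")
    return [g[fcols].to_numpy(dtype=float)
            for _, g in df.groupby("traj", sort=True)]


def write_hbond_csv(table: HBondTable, path) -> Path:
    df = table.df.copy()
    if table.state_labels is not None:
        df["state"] = np.asarray(table.state_labels)
    df.to_csv(path, index=False)
    return Path(path)


def read_hbond_csv(path) -> HBondTable:
    df = pd.read_csv(path)
    _require_columns(df, ["frame"], path)
    state = None
    if "state" in df.columns:
        state = pd.Series(df.pop("state").to_numpy(), name="state")
    table = HBondTable(df=df, state_labels=state)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# dispersion datasets and fits
# ---------------------------------------------------------------------------


def write_dispersion_csv(data: DispersionDataset, path) -> Path:
    data.points.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta_path = Path(path).with_suffix(".meta.json")
    meta_path.write_text(json.dumps(data.metadata, indent=1, sort_keys=True))
    return Path(path)


def read_dispersion_csv(path) -> DispersionDataset:
    df = pd.read_csv(path)
    _require_columns(df, DispersionDataset.COLUMNS, path)
    meta_path = Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ds = DispersionDataset(points=df, metadata=meta)
    ds.validate()
    return ds


def write_fit_json(fit: TwoStateFit, path) -> Path:
    payload = {
        "kex_s": fit.kex, "pB": fit.pB,
        "dw_ppm": {str(k): v for k, v in sorted(fit.dw_ppm.items())},
        "r20_s": {f"{r}@{f}": v for (r, f), v in sorted(fit.r20.items())},
        "chi2": fit.chi2, "redchi": fit.redchi,
        "n_params": fit.n_params, "n_points": fit.n_points,
        "r1_s": fit.r1,
        "ci": {k: list(v) for k, v in fit.ci.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    return Path(path)


# ---------------------------------------------------------------------------
# kinetic models (YAML)
# ---------------------------------------------------------------------------


def write_model_yaml(model: KineticModel, path) -> Path:
    doc = {
        "variant": model.variant,
        "timestep_ns": float(model.timestep_ns),
        "seed_policy": model.seed_policy,
        "macro_rates_per_ms": model.macro_rates.tolist(),
        "micro_T": model.micro_T.tolist(),
        "micro_to_macro": model.micro_to_macro.tolist(),
        "micro_pi": model.micro_pi.tolist(),
        "micro_feature_mean": model.micro_feature_mean.tolist(),
        "micro_feature_spread": model.micro_feature_spread.tolist(),
        "macrostates": [
            {
                "label": m.label, "loop70": m.loop70, "loop100": m.loop100,
                "population": float(m.population), "n_micro": int(m.n_micro),
                "feature_mean": np.asarray(m.feature_mean).tolist(),
                "feature_spread": np.asarray(m.feature_spread).tolist(),
                "hbond_prob": {f"{d}:{a}": float(p)
                               for (d, a), p in sorted(m.hbond_prob.items())},
                "shifts": {int(r): [float(h), float(n)]
                           for r, (h, n) in sorted(m.shifts.items())},
            }
            for m in model.macrostates
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True,
                                         default_flow_style=None))
    return Path(path)


def read_model_yaml(path) -> KineticModel:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: model document is not a mapping")
    for key in ("variant", "timestep_ns", "macro_rates_per_ms", "micro_T",
                "micro_to_macro", "micro_pi", "macrostates"):
        if key not in doc:
            raise SchemaError(f"{path}: missing model field {key!r}")
    macrostates = []
    for i, m in enumerate(doc["macrostates"]):
        for key in ("label", "loop70", "loop100", "population", "n_micro"):
            if key not in m:
                raise SchemaError(f"{path}: macrostate {i} missing {key!r}")
        macrostates.append(MacrostateSpec(
            label=m["label"], loop70=m["loop70"], loop100=m["loop100"],
            population=float(m["population"]), n_micro=int(m["n_micro"]),
            feature_mean=np.asarray(m["feature_mean"], dtype=float),
            feature_spread=np.asarray(m["feature_spread"], dtype=float),
            hbond_prob={tuple(k.split(":")): float(p)
                        for k, p in m["hbond_prob"].items()},
            shifts={int(r): (float(hn[0]), float(hn[1]))
                    for r, hn in m["shifts"].items()},
        ))
    model = KineticModel(
        variant=doc["variant"],
        macrostates=macrostates,
        macro_rates=np.asarray(doc["macro_rates_per_ms"], dtype=float),
        timestep_ns=float(doc["timestep_ns"]),
        micro_T=np.asarray(doc["micro_T"], dtype=float),
        micro_to_macro=np.asarray(doc["micro_to_macro"], dtype=np.int64),
        micro_pi=np.asarray(doc["micro_pi"], dtype=float),
        micro_feature_mean=np.asarray(doc["micro_feature_mean"], dtype=float),
        micro_feature_spread=np.asarray(doc["micro_feature_spread"],
                                        dtype=float),
        seed_policy=doc.get("seed_policy", ""),
    )
    model.validate()
    return model


def models_equal(a: KineticModel, b: KineticModel, rtol: float = 1e-12) -> bool:
    """Float-round-trip equality of two kinetic models."""
    if a.variant != b.variant or a.labels != b.labels:
        return False
    num = (
        np.allclose(a.macro_rates, b.macro_rates, rtol=rtol)
        and np.allclose(a.micro_T, b.micro_T, rtol=rtol)
        and np.allclose(a.micro_pi, b.micro_pi, rtol=rtol)
        and np.array_equal(a.micro_to_macro, b.micro_to_macro)
        and np.allclose(a.micro_feature_mean, b.micro_feature_mean, rtol=rtol)
    )
    if not num:
        return False
    for ma, mb in zip(a.macrostates, b.macrostates):
        if (ma.hbond_prob != mb.hbond_prob or ma.shifts != mb.shifts
                or ma.loop70 != mb.loop70
                or abs(ma.population - mb.population) > 1e-12):
            return False
    return True


# ---------------------------------------------------------------------------
# generic JSON results
# ---------------------------------------------------------------------------


def write_json(obj: dict, path) -> Path:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=default))
    return Path(path)


def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
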