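"""Dataset I/O and result serialization."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .binary import GSResult, LabeledDataset
from .core import RunResult

__all__ = ["DataError", "read_dataset", "write_dataset", "write_report"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_dataset(
    path,
    label_col: Optional[str] = None,
    labels_path=None,
    sep: Optional[str] = None,
) -> LabeledDataset:
    """Read a delimited samples-x-features matrix with class labels.

    Labels come either from a designated column of the matrix file
    (``label_col``) or from a separate single-column file
    (``labels_path``). The header row supplies feature names. Non-numeric
    feature cells are reported with their row/column coordinates.
    """
    if (label_col is None) == (labels_path is None):
        raise DataError("provide exactly one of label_col or labels_path")
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except Exception as exc:  # noqa: BLE001 - surface parser problems as data errors
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if label_col is not None:
        if label_col not in df.columns:
            raise DataError(f"label column {label_col!r} not found in {path}")
        y = df[label_col].to_numpy()
        features = df.drop(columns=[label_col])
    else:
        ydf = pd.read_csv(labels_path, header=None)
        y = ydf.iloc[:, 0].to_numpy()
        # a header line in the labels file would shift the length by one
        if len(y) == len(df) + 1:
            y = y[1:]
        if len(y) != len(df):
            raise DataError(
                f"labels file has {len(y)} entries but the matrix has {len(df)} rows"
            )
        features = df
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & features.notna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise DataError(
            f"non-numeric feature cell at row {r}, column {features.columns[c]!r}: "
            f"{features.iloc[r, c]!r}"
        )
    if numeric.isna().any().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        raise DataError(
            f"missing feature value at row {int(rows[0])}, "
            f"column {features.columns[int(cols[0])]!r}"
        )
    try:
        return LabeledDataset(
            X=numeric.to_numpy(dtype=float),
            y=y,
            feature_names=[str(c) for c in features.columns],
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def write_dataset(data: LabeledDataset, path, label_col: str = "class") -> None:
    """Write a dataset as CSV with the labels in a designated column."""
    names = data.feature_names or [f"f{j}" for j in range(data.n_features)]
    df = pd.DataFrame(data.X, columns=names)
    df[label_col] = data.y
    df.to_csv(path, index=False)


def _manifest(out: Path, config: dict, seeds: Sequence[int]) -> None:
    manifest = {
        "package": "smafbi",
        "version": _pkg_version,
        "config": config,
        "seeds": [int(s) for s in seeds],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_report(results, out_dir, config: Optional[dict] = None, name: str = "run") -> Path:
    """Write aggregate CSV, per-run JSON, convergence CSVs and a manifest.

    ``results`` is either a list of :class:`RunResult` (continuous
    optimization) or a :class:`GSResult` (gene selection). Returns the
    output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(results, GSResult):
        rows = []
        for i, run in enumerate(results.runs):
            rows.append(
                {
                    "run": i,
                    "seed": run.seed,
                    "n_selected": run.n_selected,
                    "reported_error": run.reported_error,
                    "cv_error": run.cv_error,
                    "best_fitness": run.best_fitness,
                    "wall_time": run.wall_time,
                }
            )
            payload = {
                **rows[-1],
                "selected_features": run.best_mask.selected().tolist(),
            }
            (out / f"{name}_run{i:03d}.json").write_text(json.dumps(payload, indent=2))
            pd.DataFrame(run.trace, columns=["evaluations", "best_fitness"]).to_csv(
                out / f"{name}_run{i:03d}_convergence.csv", index=False
            )
        pd.DataFrame(rows).to_csv(out / f"{name}_runs.csv", index=False)
        summary = results.summary()
        pd.DataFrame([summary]).to_csv(out / f"{name}_summary.csv", index=False)
        _manifest(out, config or {}, [r.seed for r in results.runs])
        return out

    if results and isinstance(results[0], RunResult):
        rows = []
        for i, run in enumerate(results):
            rows.append(
                {
                    "run": i,
                    "seed": run.seed,
                    "best_value": run.best_value,
                    "evaluations": run.evaluations,
                    "iterations": run.iterations,
                }
            )
            run.to_json(out / f"{name}_run{i:03d}.json")
            run.trace.to_csv(out / f"{name}_run{i:03d}_convergence.csv")
        df = pd.DataFrame(rows)
        df.to_csv(out / f"{name}_runs.csv", index=False)
        vals = df["best_value"].to_numpy()
        agg = {
            "runs": len(results),
            "avg": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "best": float(vals.min()),
        }
        pd.DataFrame([agg]).to_csv(out / f"{name}_summary.csv", index=False)
        _manifest(out, config or {}, [r.seed for r in results])
        return out

    # empty result list: emit header-only aggregate, no crash
    pd.DataFrame(columns=["run", "seed", "best_value"]).to_csv(
        out / f"{name}_runs.csv", index=False
    )
    _manifest(out, config or {}, [])
    return out
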