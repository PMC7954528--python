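"""Plain-text file formats and run manifests.

Everything the pipeline reads or writes is plain text: SWC for skeletons, CSV
with headers for synapse tables, trial traces, coherence values and sweep
grids, JSON for nested results, manifests and ground truth, and YAML or JSON
for run configuration.  Every output directory receives a ``manifest.json``
recording input checksums, options, seed and package version, sufficient to
re-execute the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from synarbor.coherence import CoherenceRecord, TrialRecording, coherence_frame
from synarbor.sweep import FRatioGrid

__all__ = [
    "sha256_of",
    "write_manifest",
    "save_trial",
    "load_trial",
    "write_coherence_csv",
    "read_coherence_csv",
    "read_z_values",
    "write_grid_csv",
    "read_grid_csv",
    "load_config",
    "RunConfig",
]


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _jsonable(value: Any) -> Any:
    if is_dataclass(value) and not isinstance(value, type):
        return _jsonable(asdict(value))
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, complex):
        return {"re": value.real, "im": value.imag}
    return value


def write_manifest(
    out_dir: str | Path,
    stage: str,
    inputs: Mapping[str, str | Path] | None = None,
    options: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> Path:
    """Write ``manifest.json`` for a pipeline stage into ``out_dir``."""
    from synarbor import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(path), "sha256": sha256_of(path)}
            for name, path in (inputs or {}).items()
        },
        "options": _jsonable(options or {}),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return path


# ------------------------------------------------------------------- trials


def save_trial(trial: TrialRecording, csv_path: str | Path) -> None:
    """Trial traces as a CSV matrix plus a JSON sidecar with the metadata."""
    csv_path = Path(csv_path)
    trial.traces.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    with open(sidecar, "w") as handle:
        json.dump(
            {
                "trial_id": trial.trial_id,
                "behavior": trial.behavior,
                "dt": trial.dt,
                "reference_cell": trial.reference_cell,
            },
            handle,
            indent=1,
        )
        handle.write("\n")


def load_trial(csv_path: str | Path) -> TrialRecording:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"trial sidecar {sidecar} not found")
    with open(sidecar) as handle:
        meta = json.load(handle)
    traces = pd.read_csv(csv_path)
    return TrialRecording(
        trial_id=str(meta["trial_id"]),
        behavior=str(meta["behavior"]),
        dt=float(meta["dt"]),
        traces=traces,
        reference_cell=str(meta["reference_cell"]),
    )


# ---------------------------------------------------------------- coherence


def write_coherence_csv(records: list[CoherenceRecord], path: str | Path) -> None:
    coherence_frame(records).to_csv(path, index=False)


def read_coherence_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"cell_id": str, "trial_id": str})
    required = {"cell_id", "re_z", "im_z"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"coherence table missing columns: {sorted(missing)}")
    return frame


def read_z_values(path: str | Path, trial_id: str | None = None) -> dict[str, complex]:
    """Map partner/cell id → complex coherence from a coherence CSV."""
    frame = read_coherence_csv(path)
    if trial_id is not None and "trial_id" in frame.columns:
        frame = frame[frame["trial_id"] == trial_id]
    return {
        str(row.cell_id): complex(row.re_z, row.im_z)
        for row in frame.itertuples(index=False)
    }


def write_z_values(
    z_values: Mapping[str, complex], path: str | Path, trial_id: str = ""
) -> None:
    """Write a bare partner→z map in the coherence CSV layout."""
    rows = []
    for cell, z in sorted(z_values.items()):
        rows.append(
            {
                "cell_id": cell,
                "trial_id": trial_id,
                "re_z": z.real,
                "im_z": z.imag,
                "magnitude": abs(z),
                "phase": float(np.angle(z)),
                "ci": np.nan,
                "f_star": np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------------- grids


def write_grid_csv(grid: FRatioGrid, path: str | Path) -> None:
    grid.to_long_frame().to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> FRatioGrid:
    frame = pd.read_csv(path)
    d_nn_values = tuple(sorted(frame["d_nn"].unique()))
    d_ext_values = tuple(sorted(frame["d_ext"].unique()))
    shape = (len(d_nn_values), len(d_ext_values))
    f = np.full(shape, np.nan)
    p_hat = np.full(shape, np.nan)
    n_clusters = np.zeros(shape, dtype=int)
    degenerate = np.ones(shape, dtype=bool)
    i_of = {v: i for i, v in enumerate(d_nn_values)}
    j_of = {v: j for j, v in enumerate(d_ext_values)}
    for row in frame.itertuples(index=False):
        i, j = i_of[row.d_nn], j_of[row.d_ext]
        f[i, j] = row.f
        p_hat[i, j] = row.p_hat
        n_clusters[i, j] = row.n_clusters
        degenerate[i, j] = bool(row.degenerate)
    trial_id = str(frame["trial_id"].iloc[0]) if len(frame) else ""
    return FRatioGrid(
        trial_id=trial_id,
        d_nn_values=d_nn_values,
        d_ext_values=d_ext_values,
        f=f,
        p_hat=p_hat,
        n_clusters=n_clusters,
        degenerate=degenerate,
    )


# ------------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Validated run configuration tying the pipeline stages together."""

    skeleton: Path | None = None
    synapses: Path | None = None
    trials: tuple[Path, ...] = ()
    coherence: Path | None = None
    out_dir: Path = Path("results")
    n_shuffles: int = 1000
    seed: int = 0
    alpha: float = 0.05
    spectral: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = load_config(path)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("skeleton", "synapses", "coherence"):
            if data.get(key) is not None:
                data[key] = Path(data[key])
        if "trials" in data:
            data["trials"] = tuple(Path(p) for p in data["trials"])
        if "out_dir" in data:
            data["out_dir"] = Path(data["out_dir"])
        return cls(**data)

    def validate_paths(self) -> None:
        """Check that every referenced input file exists."""
        for path in (self.skeleton, self.synapses, self.coherence, *self.trials):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input missing: {path}")

    def spectral_options(self):
        from synarbor.coherence import SpectralOptions

        return SpectralOptions(**self.spectral) if self.spectral else SpectralOptions()

    def parameter_grid(self):
        from synarbor.sweep import ParameterGrid

        if not self.grid:
            return ParameterGrid.default()
        return ParameterGrid(
            d_nn_values=tuple(self.grid["d_nn_values"]),
            d_ext_values=tuple(self.grid["d_ext_values"]),
        )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run-configuration mapping."""
    path = Path(path)
    with open(path) as handle:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(handle)
        else:
            data = json.load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
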