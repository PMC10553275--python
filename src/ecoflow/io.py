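"""File writers and readers shared by the CLI and scripts.

Output contracts:

* time-series CSV - one row per step, columns
  ``t, N_C, N_D, rho, rho_C, rho_D, m, payoff_C, payoff_D, basal_C,
  basal_D, births_C, births_D, deaths_C, deaths_D, mean_energy,
  immigration`` (immigration as 0/1).
* lifespan CSV - ``strategy, birth_time, death_time, lifespan``.
* snapshots - plain text, one block per dump: a ``# t=<step>`` header then
  L rows of L ``nC:nD`` tokens.
* metadata JSON - every parameter, the seed, the package version and the
  wall-clock start time, sufficient to regenerate every other file.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .engine import LIFESPAN_COLUMNS, TIME_SERIES_COLUMNS, RunResult
from .params import Params

__all__ = [
    "write_time_series",
    "write_lifespans",
    "write_snapshots",
    "write_metadata",
    "write_outputs",
    "read_time_series",
    "check_writable",
]


def check_writable(out_dir: str | Path) -> Path:
    """Pre-flight check: create the output directory and probe writability."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    probe.unlink()
    return out


def write_time_series(time_series: pd.DataFrame, path: str | Path) -> None:
    time_series[TIME_SERIES_COLUMNS].to_csv(path, index=False)


def write_lifespans(lifespans: pd.DataFrame, path: str | Path) -> None:
    lifespans[LIFESPAN_COLUMNS].to_csv(path, index=False)


def write_snapshots(
    snapshots: list[tuple[int, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for t, n_c, n_d in snapshots:
            fh.write(f"# t={t}\n")
            for row_c, row_d in zip(n_c, n_d):
                fh.write(
                    " ".join(f"{a}:{b}" for a, b in zip(row_c, row_d)) + "\n"
                )


def write_metadata(params: Params, path: str | Path, **extra) -> None:
    meta = {
        "params": params.to_dict(),
        "seed": params.seed,
        "version": __version__,
        "wall_start": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_outputs(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the full output file set of a run; returns the paths."""
    out = check_writable(out_dir)
    paths = {
        "time_series": out / "time_series.csv",
        "lifespans": out / "lifespans.csv",
        "metadata": out / "metadata.json",
    }
    write_time_series(result.time_series, paths["time_series"])
    write_lifespans(result.lifespans, paths["lifespans"])
    write_metadata(result.params, paths["metadata"])
    if result.snapshots:
        paths["snapshots"] = out / "snapshots.txt"
        write_snapshots(result.snapshots, paths["snapshots"])
    return paths


def read_time_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
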