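"""Tab-separated interchange formats and run configuration.

One TSV schema carries every peak-intensity measurement::

    peak_id  assignment  shift_h  shift_c  experiment  delay_ms  intensity  noise_sigma

``experiment`` is one of ``allowed``, ``forbidden`` (relaxation rows, delay
required) or ``para``, ``dia`` (PRE rows, delay empty).  Delays are
milliseconds at the file boundary and seconds internally.  Bond-vector
tables use ``time_ns  methyl_id  x  y  z``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError
from .fitting import EtaFitResult, MethylPeak, RelaxationSeries
from .mdorder import BondVectorTrajectory, OrderParameterResult
from .model import ScanCounts

logger = logging.getLogger(__name__)

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "relaxation_dataset_from_table",
    "relaxation_dataset_to_table",
    "pre_tables_from_table",
    "read_bond_vectors",
    "write_bond_vectors",
    "write_fit_results",
    "read_fit_results",
    "write_order_parameters",
]

PEAK_TABLE_COLUMNS = [
    "peak_id",
    "assignment",
    "shift_h",
    "shift_c",
    "experiment",
    "delay_ms",
    "intensity",
    "noise_sigma",
]
_EXPERIMENTS = {"allowed", "forbidden", "para", "dia"}
_RELAXATION = {"allowed", "forbidden"}


@dataclasses.dataclass
class RunConfig:
    """Declarative settings echoed into every output directory."""

    scheme: str = "reduced"
    n_bootstrap: int = 1000
    seed: int = 0
    pre_k: float = 1.0
    fold_threshold: float = 10.0
    n_allowed_scans: int = 1
    n_forbidden_scans: int = 1
    window_discard_ns: float = 25.0
    window_length_ns: float = 32.0
    window_overlap_ns: float = 28.0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.scheme not in {"full", "reduced"}:
            raise InputError(f"unknown scheme {self.scheme!r}")
        if self.n_bootstrap < 2:
            raise InputError("n_bootstrap must be >= 2")

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peak-intensity TSV; delays converted ms -> s.

    Row-level problems are collected and reported together in one error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "assignment": str})
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    bad_exp = ~df["experiment"].isin(_EXPERIMENTS)
    for idx in df.index[bad_exp]:
        problems.append(f"row {idx + 2}: unknown experiment {df.at[idx, 'experiment']!r}")
    is_relax = df["experiment"].isin(_RELAXATION)
    for idx in df.index[is_relax & df["delay_ms"].isna()]:
        problems.append(f"row {idx + 2}: relaxation row missing delay_ms")
    for idx in df.index[~is_relax & df["delay_ms"].notna()]:
        problems.append(f"row {idx + 2}: PRE row must not carry delay_ms")
    for idx in df.index[df["noise_sigma"] <= 0]:
        problems.append(f"row {idx + 2}: noise_sigma must be > 0")
    dup = df.duplicated(subset=["peak_id", "experiment", "delay_ms"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup])
        problems.append(f"duplicate (peak_id, experiment, delay_ms) at rows {rows}")
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))

    out = df.copy()
    out["delay_s"] = out["delay_ms"] * 1e-3
    return out


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a peak table (delay carried in ms; any delay_s column dropped)."""
    cols = [c for c in PEAK_TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def relaxation_dataset_to_table(dataset: list[RelaxationSeries]) -> pd.DataFrame:
    rows = []
    for s in dataset:
        for exp, data in (("allowed", s.allowed), ("forbidden", s.forbidden)):
            for delay, intensity, sigma in data:
                rows.append(
                    {
                        "peak_id": s.peak.peak_id,
                        "assignment": s.peak.assignment,
                        "shift_h": s.peak.shift_h,
                        "shift_c": s.peak.shift_c,
                        "experiment": exp,
                        "delay_ms": delay * 1e3,
                        "intensity": intensity,
                        "noise_sigma": sigma,
                    }
                )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def relaxation_dataset_from_table(
    df: pd.DataFrame, scans: ScanCounts | None = None
) -> list[RelaxationSeries]:
    """Assemble per-peak relaxation series from a validated peak table."""
    if scans is None:
        scans = ScanCounts()
    relax = df[df["experiment"].isin(_RELAXATION)]
    dataset: list[RelaxationSeries] = []
    for pid, grp in relax.groupby("peak_id", sort=True):
        first = grp.iloc[0]
        peak = MethylPeak(
            peak_id=str(pid),
            assignment=None if pd.isna(first["assignment"]) else str(first["assignment"]),
            shift_h=None if pd.isna(first["shift_h"]) else float(first["shift_h"]),
            shift_c=None if pd.isna(first["shift_c"]) else float(first["shift_c"]),
        )
        series = {}
        for exp in _RELAXATION:
            sub = grp[grp["experiment"] == exp]
            series[exp] = [
                (float(r["delay_s"]), float(r["intensity"]), float(r["noise_sigma"]))
                for _, r in sub.iterrows()
            ]
        dataset.append(
            RelaxationSeries(
                peak=peak,
                allowed=series["allowed"],
                forbidden=series["forbidden"],
                scans=scans,
            )
        )
    return dataset


def pre_tables_from_table(
    df: pd.DataFrame,
) -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
    """Extract (para, dia) intensity maps from a validated peak table."""
    out: dict[str, dict[str, tuple[float, float]]] = {"para": {}, "dia": {}}
    for exp in ("para", "dia"):
        sub = df[df["experiment"] == exp]
        for _, r in sub.iterrows():
            out[exp][str(r["peak_id"])] = (float(r["intensity"]), float(r["noise_sigma"]))
    return out["para"], out["dia"]


def read_bond_vectors(path: str | Path) -> list[BondVectorTrajectory]:
    """Read ``time_ns  methyl_id  x  y  z`` into per-methyl trajectories."""
    df = pd.read_csv(path, sep="\t", dtype={"methyl_id": str})
    needed = ["time_ns", "methyl_id", "x", "y", "z"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for mid, grp in df.groupby("methyl_id", sort=True):
        grp = grp.sort_values("time_ns")
        out.append(
            BondVectorTrajectory(
                methyl_id=str(mid),
                times=grp["time_ns"].to_numpy(),
                vectors=grp[["x", "y", "z"]].to_numpy(),
            )
        )
    return out


def write_bond_vectors(trajs: list[BondVectorTrajectory], path: str | Path) -> None:
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "time_ns": t.times,
                    "methyl_id": t.methyl_id,
                    "x": t.vectors[:, 0],
                    "y": t.vectors[:, 1],
                    "z": t.vectors[:, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_fit_results(results: list[EtaFitResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "peak_id": r.peak_id,
                "scheme": r.scheme,
                "eta": r.params.eta,
                "eta_err": r.eta_err if r.eta_err is not None else np.nan,
                "delta": r.params.delta,
                "delta_err": r.delta_err if r.delta_err is not None else np.nan,
                "r_slow": r.params.r_slow if r.params.r_slow is not None else np.nan,
                "r_fast": r.params.r_fast if r.params.r_fast is not None else np.nan,
                "amplitude": r.params.amplitude
                if r.params.amplitude is not None
                else np.nan,
                "residual_sse": r.residual_sse,
                "converged": r.converged,
                "unreliable": r.unreliable,
            }
        )
    cols = [
        "peak_id", "scheme", "eta", "eta_err", "delta", "delta_err",
        "r_slow", "r_fast", "amplitude", "residual_sse", "converged", "unreliable",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_fit_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str})
    if "eta" not in df.columns or "peak_id" not in df.columns:
        raise FormatError(f"{path}: not a fit-results table")
    return df


def write_order_parameters(
    results: list[OrderParameterResult], path: str | Path
) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "methyl_id": r.methyl_id,
                "mean_s2": r.mean_s2,
                "sd_s2": r.sd_s2 if r.sd_s2 is not None else np.nan,
                "n_windows": len(r.per_window_s2),
                "per_window_s2": ",".join(f"{v:.6g}" for v in r.per_window_s2),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
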