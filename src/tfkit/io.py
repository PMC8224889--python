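"""File I/O, results persistence and run logging.

Signals travel as two-column plain-text files (time, value; any
delimiter) or HDF5 datasets (time grid from a companion dataset or
from ``start``/``dt`` attributes). A completed analysis is captured in
a :class:`ResultsRecord` holding provenance, the per-run table, the
selected kernel and the (pre-treated) signal pair, and can be exported
either as a delimited spreadsheet readable by any Excel-like program
or as a self-describing HDF5 archive that round-trips losslessly:
re-loading an archive and re-scoring its selected kernel reproduces
the stored residual and Pearson values exactly.

All values are written as 64-bit floats; delimited exports use full
``repr`` precision. Errors raised while reading or writing are also
appended to the run log (see :func:`setup_run_log`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from ._version import __version__
from .evaluation import pearson, predict, rss
from .optimization import RunResult
from .signals import TimeSeries

__all__ = [
    "TimeSeriesParseError",
    "MonotonicityError",
    "read_timeseries_text",
    "write_timeseries_text",
    "read_timeseries_hdf5",
    "write_timeseries_hdf5",
    "ResultsRecord",
    "export_results",
    "load_results",
    "setup_run_log",
]

logger = logging.getLogger("tfkit")


class TimeSeriesParseError(ValueError):
    """A text file did not contain enough parseable (time, value) rows."""


class MonotonicityError(ValueError):
    """Parsed time stamps are not strictly increasing."""


def setup_run_log(path: str | Path) -> logging.Logger:
    """Attach a file handler so warnings and errors land in a run log."""
    handler = logging.FileHandler(path)
    handler.setLevel(logging.WARNING)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.WARNING)
    return logger


def read_timeseries_text(
    path: str | Path,
    time_col: int = 0,
    value_col: int = 1,
    delimiter: Optional[str] = None,
) -> TimeSeries:
    """Parse a two-column (time, value) plain-text file.

    Rows that fail numeric parsing (headers, comments, malformed lines)
    are skipped and reported with their line numbers in the run log.
    Raises :class:`TimeSeriesParseError` when fewer than 2 rows parse
    and :class:`MonotonicityError` when times are out of order.
    """
    path = Path(path)
    if not path.exists():
        err = FileNotFoundError(f"no such signal file: {path}")
        logger.error("%s", err)
        raise err
    times: List[float] = []
    values: List[float] = []
    bad_lines: List[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            try:
                t = float(parts[time_col])
                v = float(parts[value_col])
            except (ValueError, IndexError):
                bad_lines.append(lineno)
                continue
            times.append(t)
            values.append(v)
    if bad_lines and bad_lines != [1]:  # a lone first bad row is a header
        logger.warning(
            "%s: skipped %d unparseable line(s): %s",
            path,
            len(bad_lines),
            bad_lines[:20],
        )
    if len(times) < 2:
        err = TimeSeriesParseError(
            f"{path}: found {len(times)} parseable (time, value) rows; "
            "at least 2 are required"
        )
        logger.error("%s", err)
        raise err
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        err = MonotonicityError(
            f"{path}: time stamps are not strictly increasing"
        )
        logger.error("%s", err)
        raise err
    return TimeSeries(t, np.asarray(values))


def write_timeseries_text(
    path: str | Path,
    ts: TimeSeries,
    delimiter: str = "\t",
    header: Optional[str] = "time\tvalue",
) -> None:
    """Write a series as delimited text at full repr precision."""
    lines = []
    if header:
        lines.append(header)
    for t, v in zip(ts.times, ts.values):
        lines.append(f"{float(t)!r}{delimiter}{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _available_datasets(h5: h5py.File) -> List[str]:
    names: List[str] = []
    h5.visititems(
        lambda name, obj: names.append(name)
        if isinstance(obj, h5py.Dataset)
        else None
    )
    return names


def read_timeseries_hdf5(
    path: str | Path,
    dataset: str,
    times_dataset: Optional[str] = None,
) -> TimeSeries:
    """Read a series from an HDF5 file.

    ``dataset`` holds the values. The time grid comes either from a
    companion ``times_dataset`` or, when omitted, from ``start`` and
    ``dt`` attributes on the values dataset (an arithmetic grid
    ``start, start + dt, ...``). A missing dataset path raises a
    ``KeyError`` listing the datasets the file does contain.
    """
    with h5py.File(path, "r") as h5:
        if dataset not in h5:
            available = _available_datasets(h5)
            err = KeyError(
                f"dataset {dataset!r} not found in {path}; "
                f"available datasets: {available}"
            )
            logger.error("%s", err)
            raise err
        dset = h5[dataset]
        values = np.asarray(dset[()], dtype=np.float64)
        if values.ndim != 1:
            raise ValueError(f"dataset {dataset!r} is not 1-D")
        if times_dataset is not None:
            if times_dataset not in h5:
                available = _available_datasets(h5)
                err = KeyError(
                    f"times dataset {times_dataset!r} not found in {path}; "
                    f"available datasets: {available}"
                )
                logger.error("%s", err)
                raise err
            times = np.asarray(h5[times_dataset][()], dtype=np.float64)
        else:
            if "dt" not in dset.attrs:
                raise ValueError(
                    f"dataset {dataset!r} has no 'dt' attribute and no "
                    "companion times dataset was given"
                )
            dt = float(dset.attrs["dt"])
            start = float(dset.attrs.get("start", 0.0))
            times = start + dt * np.arange(values.size)
    return TimeSeries(times, values)


def write_timeseries_hdf5(
    path: str | Path,
    ts: TimeSeries,
    dataset: str = "values",
    times_dataset: Optional[str] = "times",
    mode: str = "w",
) -> None:
    """Write a series to HDF5 (values + companion times, or start/dt attrs)."""
    with h5py.File(path, mode) as h5:
        dset = h5.create_dataset(dataset, data=ts.values, dtype=np.float64)
        if times_dataset is not None:
            h5.create_dataset(times_dataset, data=ts.times, dtype=np.float64)
        dt = ts.dt
        if dt is not None:
            dset.attrs["dt"] = dt
            dset.attrs["start"] = float(ts.times[0])


@dataclass
class ResultsRecord:
    """Provenance, run table, selected TF and the scored signal pair.

    The stored ``input_ts``/``output_ts`` are the *pre-treated* series
    the kernels were scored against, so re-scoring the selected TF
    after a round trip reproduces the stored residual and Pearson
    exactly.
    """

    provenance: Dict
    runs: List[RunResult]
    selected_tf: TimeSeries
    input_ts: TimeSeries
    output_ts: TimeSeries
    residual: float
    pearson_r: float
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def from_selection(
        cls,
        provenance: Dict,
        runs: Sequence[RunResult],
        selected_tf: TimeSeries,
        input_ts: TimeSeries,
        output_ts: TimeSeries,
    ) -> "ResultsRecord":
        pred = predict(input_ts, selected_tf)
        return cls(
            provenance=dict(provenance),
            runs=list(runs),
            selected_tf=selected_tf,
            input_ts=input_ts,
            output_ts=output_ts,
            residual=rss(pred, output_ts),
            pearson_r=pearson(pred, output_ts),
        )

    def rescore(self) -> Tuple[float, float]:
        """Recompute (residual, pearson) of the selected TF from scratch."""
        pred = predict(self.input_ts, self.selected_tf)
        return rss(pred, self.output_ts), pearson(pred, self.output_ts)


def _runs_table_lines(runs: Sequence[RunResult], delimiter: str) -> List[str]:
    header = [
        "run",
        "algorithm",
        "seed",
        "residual",
        "pearson",
        "consistent",
        "n_cost_evals",
        "error",
        "params",
    ]
    lines = [delimiter.join(header)]
    for i, r in enumerate(runs):
        fields = [
            str(i),
            r.algorithm,
            "" if r.seed is None else str(r.seed),
            repr(float(r.residual)),
            repr(float(r.pearson)),
            str(bool(r.consistent)),
            str(r.n_cost_evals),
            r.error or "",
            " ".join(repr(float(p)) for p in r.params),
        ]
        lines.append(delimiter.join(fields))
    return lines


def export_results(
    record: ResultsRecord, path: str | Path, fmt: Optional[str] = None
) -> Path:
    """Export a record as a delimited spreadsheet or an HDF5 archive.

    ``fmt`` is ``"csv"`` (section-structured delimited text, openable
    by any Excel-like software) or ``"hdf5"`` (lossless native
    archive); when omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    try:
        if fmt == "csv":
            _export_csv(record, path)
        elif fmt == "hdf5":
            _export_hdf5(record, path)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    except OSError as err:
        logger.error("export to %s failed: %s", path, err)
        raise
    return path


def _export_csv(record: ResultsRecord, path: Path, delimiter: str = ",") -> None:
    lines: List[str] = ["# provenance"]
    meta = dict(record.provenance)
    meta["software_version"] = record.version
    meta["timestamp"] = record.timestamp
    meta["selected_residual"] = repr(record.residual)
    meta["selected_pearson"] = repr(record.pearson_r)
    for key in sorted(meta):
        lines.append(f"{key}{delimiter}{meta[key]}")
    lines.append("")
    lines.append("# runs")
    lines.extend(_runs_table_lines(record.runs, delimiter))
    lines.append("")
    lines.append("# selected_tf")
    lines.append(f"time{delimiter}value")
    for t, v in zip(record.selected_tf.times, record.selected_tf.values):
        lines.append(f"{float(t)!r}{delimiter}{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def _write_series_group(h5: h5py.File, name: str, ts: TimeSeries) -> None:
    grp = h5.create_group(name)
    grp.create_dataset("times", data=ts.times, dtype=np.float64)
    grp.create_dataset("values", data=ts.values, dtype=np.float64)


def _read_series_group(h5: h5py.File, name: str) -> TimeSeries:
    grp = h5[name]
    return TimeSeries(np.asarray(grp["times"]), np.asarray(grp["values"]))


def _export_hdf5(record: ResultsRecord, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["provenance_json"] = json.dumps(record.provenance)
        h5.attrs["software_version"] = record.version
        h5.attrs["timestamp"] = record.timestamp
        h5.attrs["residual"] = record.residual
        h5.attrs["pearson"] = record.pearson_r
        _write_series_group(h5, "selected_tf", record.selected_tf)
        _write_series_group(h5, "input", record.input_ts)
        _write_series_group(h5, "output", record.output_ts)
        n = len(record.runs)
        grp = h5.create_group("runs")
        if n:
            width = max(len(r.params) for r in record.runs)
            params = np.full((n, width), np.nan)
            for i, r in enumerate(record.runs):
                params[i, : len(r.params)] = r.params
            grp.create_dataset("params", data=params, dtype=np.float64)
            grp.create_dataset(
                "residual", data=[r.residual for r in record.runs]
            )
            grp.create_dataset(
                "pearson", data=[r.pearson for r in record.runs]
            )
            grp.create_dataset(
                "consistent",
                data=[bool(r.consistent) for r in record.runs],
            )
            grp.create_dataset(
                "seed",
                data=[-1 if r.seed is None else r.seed for r in record.runs],
            )
            grp.create_dataset(
                "n_cost_evals", data=[r.n_cost_evals for r in record.runs]
            )
            grp.create_dataset(
                "algorithm",
                data=[r.algorithm for r in record.runs],
                dtype=h5py.string_dtype(),
            )
            grp.create_dataset(
                "error",
                data=[r.error or "" for r in record.runs],
                dtype=h5py.string_dtype(),
            )


def load_results(path: str | Path) -> ResultsRecord:
    """Load an HDF5 results archive back into a :class:`ResultsRecord`."""
    with h5py.File(path, "r") as h5:
        runs: List[RunResult] = []
        grp = h5["runs"]
        if "params" in grp:
            n = grp["params"].shape[0]
            for i in range(n):
                params = np.asarray(grp["params"][i])
                params = params[~np.isnan(params)]
                seed = int(grp["seed"][i])
                error = grp["error"][i].decode() or None
                runs.append(
                    RunResult(
                        params=params,
                        residual=float(grp["residual"][i]),
                        pearson=float(grp["pearson"][i]),
                        consistent=bool(grp["consistent"][i]),
                        algorithm=grp["algorithm"][i].decode(),
                        seed=None if seed < 0 else seed,
                        n_cost_evals=int(grp["n_cost_evals"][i]),
                        error=error,
                    )
                )
        return ResultsRecord(
            provenance=json.loads(h5.attrs["provenance_json"]),
            runs=runs,
            selected_tf=_read_series_group(h5, "selected_tf"),
            input_ts=_read_series_group(h5, "input"),
            output_ts=_read_series_group(h5, "output"),
            residual=float(h5.attrs["residual"]),
            pearson_r=float(h5.attrs["pearson"]),
            version=str(h5.attrs["software_version"]),
            timestamp=str(h5.attrs["timestamp"]),
        )
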