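"""Readers, writers and the shared data model.

All tabular inputs are plain-text delimited files (comma, tab or semicolon;
the delimiter is sniffed). Times are converted to seconds on load: a time
column whose name carries a ``min``/``h`` unit token is rescaled, everything
else is taken to be seconds already. All in-memory times are seconds.
"""

from __future__ import annotations

import io as _io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("phasekin")

_DELIMITERS = (",", "\t", ";")

#: maximum run of consecutive missing points repaired by linear interpolation
MAX_INTERP_GAP = 2


class FormatError(ValueError):
    """The file could not be parsed into the expected schema."""


class ValidationError(ValueError):
    """The file parsed but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class ThTTrace:
    """One well's ThT fluorescence time course.

    ``time_s`` is strictly increasing, in seconds; ``intensity`` is the
    instrument's arbitrary fluorescence unit. ``condition`` / ``molar_ratio``
    / ``substrate_conc_uM`` carry assay metadata and do not affect fitting.
    """

    well_id: str
    time_s: np.ndarray
    intensity: np.ndarray
    condition: str = ""
    molar_ratio: str | None = None
    substrate_conc_uM: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.intensity.shape:
            raise ValidationError(f"well {self.well_id}: time and intensity must be 1-D and equal length")
        if len(self.time_s) < 10:
            raise ValidationError(f"well {self.well_id}: need >= 10 points, got {len(self.time_s)}")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError(f"well {self.well_id}: time not strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError(f"well {self.well_id}: missing/non-finite intensity after load")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PlateKinetics:
    """A plate of ThT traces on a (near-)common time grid."""

    traces: list[ThTTrace]
    cycle_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.well_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dup = sorted({w for w in ids if ids.count(w) > 1})
            raise ValidationError(f"duplicate well id(s): {', '.join(dup)}")
        if self.traces:
            ref = self.traces[0].time_s
            tol = max(1e-6, 1e-3 * self.cycle_s)
            for tr in self.traces[1:]:
                if len(tr) != len(ref) or np.max(np.abs(tr.time_s - ref)) > tol:
                    raise ValidationError(f"well {tr.well_id}: time grid differs from plate grid")

    def __len__(self) -> int:
        return len(self.traces)

    def well(self, well_id: str) -> ThTTrace:
        for tr in self.traces:
            if tr.well_id == well_id:
                return tr
        raise KeyError(well_id)


@dataclass
class FrapSeries:
    """Raw three-ROI photobleaching series (bleached ROI, whole-condensate
    reference, off-condensate background) with the first post-bleach frame."""

    time_s: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time_s", "roi", "reference", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if not (len(self.roi) == len(self.reference) == len(self.background) == n):
            raise ValidationError("frap series: all four columns must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("frap series: time not strictly increasing")
        if not (1 <= self.bleach_index < n):
            raise ValidationError(f"bleach_index {self.bleach_index} outside 1..{n - 1}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PhotonTrace:
    """Binned photon counts from one detection channel."""

    bin_width_ms: float
    counts: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValidationError("photon counts must be non-negative")
        self.counts = np.rint(counts).astype(np.int64)
        if self.bin_width_ms <= 0:
            raise ValidationError("bin_width_ms must be > 0")
        if len(self.counts) < 100:
            raise ValidationError(f"need >= 100 bins, got {len(self.counts)}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_s(self) -> float:
        return len(self.counts) * self.bin_width_ms / 1e3

    def bin_centers_ms(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width_ms


@dataclass
class TurbiditySeries:
    """Optical-density time course of one well at one or more wavelengths."""

    well_id: str
    time_s: np.ndarray
    od: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError(f"well {self.well_id}: time not strictly increasing")
        self.od = {str(k): np.asarray(v, dtype=float) for k, v in self.od.items()}
        for wl, vals in self.od.items():
            if len(vals) != len(self.time_s):
                raise ValidationError(f"well {self.well_id}: OD({wl}) length mismatch")
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"well {self.well_id}: non-finite OD at {wl} nm")

    def __len__(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    counts = {d: first.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


_UNIT_FACTORS = {
    "s": 1.0, "sec": 1.0, "secs": 1.0, "second": 1.0, "seconds": 1.0,
    "min": 60.0, "mins": 60.0, "minute": 60.0, "minutes": 60.0,
    "h": 3600.0, "hr": 3600.0, "hrs": 3600.0, "hour": 3600.0, "hours": 3600.0,
}


def time_unit_factor(column_name: str) -> float:
    """Seconds-per-unit implied by a column name (``time_min`` -> 60)."""
    tokens = re.split(r"[^a-z]+", column_name.lower())
    for tok in reversed([t for t in tokens if t]):
        if tok in _UNIT_FACTORS:
            return _UNIT_FACTORS[tok]
    return 1.0


def _read_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a delimited text file; returns (frame, leading '#' comment lines)."""
    path = Path(path)
    text = path.read_text()
    comments = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    if not body.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(body)
    header = body.splitlines()[0].split(sep)
    names = [h.strip() for h in header]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicated column(s): {', '.join(dup)}")
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep, skipinitialspace=True)
    except Exception as exc:  # pandas raises many flavours; report first bad row
        m = re.search(r"line (\d+)", str(exc))
        where = f" at line {m.group(1)}" if m else ""
        raise FormatError(f"{path}: unparseable{where}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df, comments


def _repair_gaps(y: np.ndarray, well_id: str) -> np.ndarray:
    """Linearly interpolate runs of <= MAX_INTERP_GAP missing points."""
    y = np.asarray(y, dtype=float)
    bad = ~np.isfinite(y)
    if not bad.any():
        return y
    # reject leading/trailing gaps and long runs
    runs = np.diff(np.flatnonzero(np.concatenate(([True], np.diff(bad), [True]))))
    run_vals = bad[np.cumsum(np.concatenate(([0], runs)))[:-1]]
    if bad[0] or bad[-1] or np.any(runs[run_vals] > MAX_INTERP_GAP):
        raise ValidationError(
            f"well {well_id}: missing-value gap longer than {MAX_INTERP_GAP} points")
    idx = np.arange(len(y))
    y = y.copy()
    y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    log.warning("well %s: interpolated %d missing point(s)", well_id, int(bad.sum()))
    return y


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_plate_kinetics(path: str | Path, layout: str = "wide") -> PlateKinetics:
    """Read a plate-reader kinetic export.

    ``wide``: first column is time, every further column one well.
    ``long``: columns (well, time, value), rows in any order.
    Wells whose values are entirely missing are dropped with a warning.
    """
    df, _ = _read_table(path)
    if layout == "wide":
        tcol = df.columns[0]
        time_s = df[tcol].to_numpy(dtype=float) * time_unit_factor(tcol)
        wells = {str(c): df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    elif layout == "long":
        cols = {c.lower(): c for c in df.columns}
        missing = [k for k in ("well", "time", "value") if not any(c.startswith(k) for c in cols)]
        if missing:
            raise FormatError(f"{path}: long layout needs columns well,time,value (missing {missing})")
        wcol = next(cols[c] for c in cols if c.startswith("well"))
        tcol = next(cols[c] for c in cols if c.startswith("time"))
        vcol = next(cols[c] for c in cols if c.startswith("value"))
        fac = time_unit_factor(tcol)
        df = df.sort_values([wcol, tcol], kind="mergesort")
        grids, wells = [], {}
        for well, sub in df.groupby(wcol, sort=True):
            grids.append(sub[tcol].to_numpy(dtype=float) * fac)
            wells[str(well)] = sub[vcol].to_numpy(dtype=float)
        time_s = grids[0]
        for g in grids[1:]:
            if len(g) != len(time_s) or np.max(np.abs(g - time_s)) > 1e-6 * max(1.0, time_s[-1]):
                raise ValidationError(f"{path}: wells are not on a common time grid")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if not np.all(np.diff(time_s) > 0):
        raise ValidationError(f"{path}: time not strictly increasing")

    traces = []
    for well, vals in wells.items():
        if not np.any(np.isfinite(vals)):
            log.warning("well %s: all values missing, dropped", well)
            continue
        traces.append(ThTTrace(well_id=well, time_s=time_s, intensity=_repair_gaps(vals, well)))
    if not traces:
        raise ValidationError(f"{path}: no usable wells")
    cycle_s = float(np.median(np.diff(time_s)))
    return PlateKinetics(traces=traces, cycle_s=cycle_s, meta={"source": str(path)})


def infer_bleach_index(roi: np.ndarray, min_drop_frac: float = 0.1) -> int:
    """Index of the first post-bleach frame: the largest single-frame drop.

    The drop must remove at least ``min_drop_frac`` of the running pre-drop
    level, otherwise no bleach is detectable.
    """
    roi = np.asarray(roi, dtype=float)
    d = np.diff(roi)
    i = int(np.argmin(d))
    pre = float(np.median(roi[: i + 1]))
    if pre <= 0 or -d[i] < min_drop_frac * pre:
        raise ValidationError("no detectable bleach drop and no bleach_index header")
    return i + 1


def read_frap_table(path: str | Path) -> FrapSeries:
    """Read a three-ROI recovery table (columns time, roi, reference,
    background). ``# bleach_index=N`` in a leading comment line overrides
    inference from the largest ROI drop."""
    df, comments = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    need = {"time": None, "roi": "roi", "reference": "reference", "background": "background"}
    tcol = next((cols[c] for c in cols if c.startswith("time")), None)
    if tcol is None:
        raise FormatError(f"{path}: missing 'time' column")
    for key in ("roi", "reference", "background"):
        if key not in cols:
            raise FormatError(f"{path}: missing '{key}' column")
    bleach_index = None
    for ln in comments:
        m = re.search(r"bleach_index\s*=\s*(\d+)", ln)
        if m:
            bleach_index = int(m.group(1))
    roi = df[cols["roi"]].to_numpy(dtype=float)
    if bleach_index is None:
        bleach_index = infer_bleach_index(roi)
    return FrapSeries(
        time_s=df[tcol].to_numpy(dtype=float) * time_unit_factor(tcol),
        roi=roi,
        reference=df[cols["reference"]].to_numpy(dtype=float),
        background=df[cols["background"]].to_numpy(dtype=float),
        bleach_index=bleach_index,
        meta={"source": str(path)},
    )


def read_photon_trace(path: str | Path, bin_width_ms: float, channel: str = "") -> PhotonTrace:
    """Read a binned photon-count trace.

    One column: counts at the stated bin width. Two columns (time, count):
    counts are re-binned by summation onto ``bin_width_ms`` bins (the
    requested width must be an integer multiple of the file's spacing).
    Time columns are milliseconds unless the name carries an ``s`` unit.
    """
    df, _ = _read_table(path)
    if df.shape[1] == 1:
        counts = df.iloc[:, 0].to_numpy(dtype=float)
    elif df.shape[1] == 2:
        tcol = df.columns[0]
        fac = 1e3 * time_unit_factor(tcol) if re.search(r"[_(\s]s\)?$|second", tcol.lower()) else 1.0
        t = df[tcol].to_numpy(dtype=float) * fac
        dt = float(np.median(np.diff(t)))
        ratio = bin_width_ms / dt
        n_per = int(round(ratio))
        if n_per < 1 or abs(ratio - n_per) > 1e-6:
            raise FormatError(
                f"{path}: requested bin width {bin_width_ms} ms is not an integer "
                f"multiple of the file spacing {dt} ms")
        raw = df.iloc[:, 1].to_numpy(dtype=float)
        n_full = (len(raw) // n_per) * n_per
        counts = raw[:n_full].reshape(-1, n_per).sum(axis=1)
    else:
        raise FormatError(f"{path}: expected 1 (counts) or 2 (time,count) columns, got {df.shape[1]}")
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative counts")
    return PhotonTrace(bin_width_ms=bin_width_ms, counts=counts, channel=channel)


def read_turbidity_series(path: str | Path) -> TurbiditySeries:
    """Read a turbidity export: a time column plus one ``od_<wavelength>``
    column per wavelength (e.g. ``od_340``)."""
    df, _ = _read_table(path)
    tcol = df.columns[0]
    time_s = df[tcol].to_numpy(dtype=float) * time_unit_factor(tcol)
    od = {}
    for c in df.columns[1:]:
        m = re.match(r"od[_\s]*(\w+)", c.lower())
        od[m.group(1) if m else c] = df[c].to_numpy(dtype=float)
    if not od:
        raise FormatError(f"{path}: no OD columns")
    well = Path(path).stem
    return TurbiditySeries(well_id=well, time_s=time_s, od=od)


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read a per-well event table (columns well, group, event, time)."""
    df, _ = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for key in ("well", "group", "event", "time"):
        if not any(c.startswith(key) for c in cols):
            raise FormatError(f"{path}: missing '{key}' column")
    tcol = next(cols[c] for c in cols if c.startswith("time"))
    out = pd.DataFrame({
        "well": df[next(cols[c] for c in cols if c.startswith("well"))].astype(str),
        "group": df[next(cols[c] for c in cols if c.startswith("group"))].astype(str),
        "event": df[next(cols[c] for c in cols if c.startswith("event"))].astype(int),
        "time_s": df[tcol].to_numpy(dtype=float) * time_unit_factor(tcol),
    })
    if (out["time_s"] <= 0).any():
        raise ValidationError(f"{path}: event/censor times must be > 0")
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_plate_kinetics(plate: PlateKinetics, path: str | Path) -> None:
    """Write a plate in wide layout (time_s first, one column per well)."""
    data = {"time_s": plate.traces[0].time_s}
    for tr in plate.traces:
        data[tr.well_id] = tr.intensity
    pd.DataFrame(data).to_csv(path, index=False)


def write_frap_table(series: FrapSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bleach_index={series.bleach_index}\n")
        pd.DataFrame({
            "time_s": series.time_s, "roi": series.roi,
            "reference": series.reference, "background": series.background,
        }).to_csv(fh, index=False)


def write_photon_trace(trace: PhotonTrace, path: str | Path) -> None:
    pd.DataFrame({"counts": trace.counts}).to_csv(path, index=False)


def write_turbidity_series(series: TurbiditySeries, path: str | Path) -> None:
    data = {"time_s": series.time_s}
    for wl, vals in series.od.items():
        data[f"od_{wl}"] = vals
    pd.DataFrame(data).to_csv(path, index=False)


def write_run_summary(path: str | Path, summary: Mapping) -> None:
    """Write the JSON run summary next to the tidy result tables."""
    Path(path).write_text(json.dumps(summary, indent=2, default=str) + "\n")
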