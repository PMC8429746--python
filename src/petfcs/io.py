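"""Plain-text I/O for correlation curves, intensity traces and fit reports.

Curve format: CSV with ``#``-prefixed header lines, the first being the
column declaration ``# lag_s,g,g_se``, followed by ``# key=value`` metadata
(duration, provenance, ...).  G is stored baseline-free.  An ALV-ASC-like
instrument dialect (header block, then a correlation section of lag/value
pairs) can be read with :func:`read_alv_asc`; its +1 baseline convention is
auto-detected and subtracted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fitting import ACFModelFit, SelectionReport
from .synthetic import CorrelationCurve, IntensityTrace

logger = logging.getLogger("petfcs")

__all__ = [
    "write_curve", "read_curve", "read_alv_asc",
    "write_trace", "read_trace",
    "write_fit_json", "read_fit_json", "fits_to_table",
]


def write_curve(curve: CorrelationCurve, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# lag_s,g,g_se\n")
        if curve.duration is not None:
            fh.write(f"# duration={curve.duration!r}\n")
        if curve.mean_count_rate is not None:
            fh.write(f"# mean_count_rate={curve.mean_count_rate!r}\n")
        if curve.provenance:
            fh.write(f"# provenance={curve.provenance}\n")
        se = curve.g_se if curve.g_se is not None else [None] * len(curve)
        for lag, g, s in zip(curve.lags, curve.g, se):
            tail = f"{float(s)!r}" if s is not None else ""
            fh.write(f"{float(lag)!r},{float(g)!r},{tail}\n")


def read_curve(path: Union[str, Path]) -> CorrelationCurve:
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            rows.append((float(parts[0]), float(parts[1]),
                         float(parts[2]) if len(parts) > 2 and parts[2] else np.nan))
    arr = np.array(rows)
    g_se = arr[:, 2]
    g_se = None if np.all(np.isnan(g_se)) else g_se
    duration = float(meta["duration"]) if "duration" in meta else None
    rate = float(meta["mean_count_rate"]) if "mean_count_rate" in meta else None
    return CorrelationCurve(lags=arr[:, 0], g=arr[:, 1], g_se=g_se,
                            duration=duration, mean_count_rate=rate,
                            provenance=meta.get("provenance", str(path)))


def read_alv_asc(path: Union[str, Path], lag_unit: float = 1e-3) -> CorrelationCurve:
    """Read an ALV-ASC-like correlator export.

    The file is a free-form header block followed by a section whose title
    line contains ``Correlation``; that section holds whitespace-separated
    lag/value pairs (lags in milliseconds by default; override with
    ``lag_unit`` in seconds).  Hardware correlators of this family report
    ``g(2)(τ) = 1 + G(τ)``; when the curve's tail plateaus near 1 the +1
    baseline is subtracted (logged), so the returned curve is baseline-free.
    """
    path = Path(path)
    lags, values = [], []
    in_corr = False
    duration = None
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            stripped = line.strip('"')
            if not in_corr:
                if stripped.lower().startswith("correlation"):
                    in_corr = True
                elif stripped.lower().startswith("duration"):
                    try:
                        duration = float(stripped.split(":")[1].split()[0])
                    except (IndexError, ValueError):
                        pass
                continue
            parts = line.replace(",", " ").split()
            try:
                pair = [float(p) for p in parts[:2]]
            except ValueError:
                break  # next section
            if len(pair) < 2:
                break
            lags.append(pair[0])
            values.append(pair[1])
    if not lags:
        raise ValueError(f"no correlation section found in {path}")
    g = np.asarray(values, dtype=float)
    tail = g[-max(3, len(g) // 10):]
    if np.median(tail) > 0.5:
        logger.info("subtracting +1 baseline from %s (tail median %.3f)",
                    path, float(np.median(tail)))
        g = g - 1.0
    return CorrelationCurve(
        lags=np.asarray(lags, dtype=float) * lag_unit, g=g,
        duration=duration, provenance=f"alv_asc:{path}")


def write_trace(trace: IntensityTrace, path: Union[str, Path]) -> None:
    """Integer CSV, one column per channel, with a key=value header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bin_width={trace.bin_width!r}\n")
        if trace.seed is not None:
            fh.write(f"# seed={trace.seed}\n")
        for row in trace.counts.T:
            fh.write(",".join(str(int(c)) for c in row) + "\n")


def read_trace(path: Union[str, Path]) -> IntensityTrace:
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            rows.append([int(p) for p in line.split(",")])
    counts = np.array(rows, dtype=np.int64).T
    return IntensityTrace(bin_width=float(meta["bin_width"]), counts=counts,
                          seed=int(meta["seed"]) if "seed" in meta else None)


def write_fit_json(obj: Union[ACFModelFit, SelectionReport],
                   path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj.to_dict(), indent=2, default=float))


def read_fit_json(path: Union[str, Path]) -> ACFModelFit:
    d = json.loads(Path(path).read_text())
    if "selected" in d:
        d = d["selected"]
    return ACFModelFit.from_dict(d)


def fits_to_table(fits: dict, max_phases: Optional[int] = None) -> pd.DataFrame:
    """Flat amplitude/time-constant table, one column per condition and one
    ``a_n``/``tau_n`` row pair per phase (phases sorted by decreasing τ)."""
    if max_phases is None:
        max_phases = max((f.n_exp for f in fits.values()), default=0)
    index = ["n_molecules", "tau_d_s"]
    for i in range(1, max_phases + 1):
        index += [f"a{i}", f"tau{i}_s"]
    data = {}
    for label, fit in fits.items():
        col = [fit.diffusion.n_molecules, fit.diffusion.tau_d]
        for i in range(max_phases):
            if i < fit.n_exp:
                col += [fit.phases[i].amplitude, fit.phases[i].tau]
            else:
                col += [np.nan, np.nan]
        data[label] = col
    return pd.DataFrame(data, index=index)
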