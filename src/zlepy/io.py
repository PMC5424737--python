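"""Signal readers/writers and the standard preprocessing chain.

Supported on-disk formats:

* two-column CSV ``time,value`` (sampling rate inferred from the time column,
  which must be uniform);
* single-column CSV of values, with the sampling rate supplied by the caller.

Preprocessing is a causal third-order Butterworth band-pass (0.5–10 Hz by
default) followed by flagging an initial burn-in (default 10 s) as excluded
from analysis — the adaptive frequency estimator downstream needs that long
to converge.  The band-pass is deliberately single-pass (causal): the
zero-phase property is the enhancer's job, and a causal front-end keeps the
streaming path realizable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal import Signal

__all__ = ["read_signal", "write_signal", "preprocess"]


def preprocess(
    u: Signal,
    low_hz: float = 0.5,
    high_hz: float = 10.0,
    order: int = 3,
    burn_in_s: float = 10.0,
) -> Signal:
    """Band-pass filter and flag the initial burn-in.

    The returned signal has the same length; ``valid_from`` marks the first
    sample considered valid for analysis (burn_in_s * fs samples are flagged,
    not dropped).
    """
    if not (0 < low_hz < high_hz < u.fs / 2):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 = {u.fs / 2}"
        )
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass", fs=u.fs, output="sos")
    y = sps.sosfilt(sos, u.samples)
    return Signal(y, u.fs, valid_from=min(u.n, int(round(burn_in_s * u.fs))))


def read_signal(
    path: str | Path, format: str = "auto", fs_override: float | None = None
) -> Signal:
    """Read a signal from CSV.

    ``format``: ``"csv"`` (two columns time,value), ``"csv1"`` (one value
    column, requires ``fs_override``) or ``"auto"`` (decide from the column
    count).  A header line is tolerated.
    """
    path = Path(path)
    if format == "wfdb":
        raise ValueError("WFDB input is not supported by this build; convert to CSV")
    if format not in ("auto", "csv", "csv1"):
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(
            path, header=None, comment="#", skip_blank_lines=True,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    # tolerate a header row of non-numeric labels
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric field in {path}: {exc}") from exc
    ncol = df.shape[1]
    if format == "auto":
        format = "csv" if ncol >= 2 else "csv1"
    if format == "csv":
        if ncol < 2:
            raise ValueError(f"{path}: expected two columns (time, value), found {ncol}")
        t = df.iloc[:, 0].to_numpy()
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise ValueError(f"{path}: time column is not uniformly increasing")
        fs = fs_override if fs_override is not None else 1.0 / float(np.mean(dt))
        return Signal(df.iloc[:, 1].to_numpy(), fs)
    if fs_override is None:
        raise ValueError(f"{path}: single-column CSV requires an explicit sampling rate")
    return Signal(df.iloc[:, 0].to_numpy(), fs_override)


def write_signal(
    path: str | Path, s: Signal, format: str = "csv", header: str | None = None
) -> None:
    """Write a signal as CSV at full precision (lossless round trip).

    ``format="csv"`` writes time,value rows; ``"csv1"`` writes values only.
    An optional header string is emitted as ``#``-prefixed comment lines.
    """
    if format not in ("csv", "csv1"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if format == "csv":
            for i, v in enumerate(s.samples):
                fh.write(f"{i / s.fs:.17g},{v:.17g}\n")
        else:
            fh.write(f"# fs_hz: {s.fs:.17g}\n")
            for v in s.samples:
                fh.write(f"{v:.17g}\n")
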