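"""Time-indexed measurement curves and their delimited-text round trip.

A :class:`Curve` holds a strictly increasing time column, a primary signal
(indentation force in nN or aspirated length in um), an optional driver
signal (indentation depth in um or applied pressure in MPa) and free-form
metadata.  On disk a curve is a TSV file with ``#key=value`` metadata lines
followed by a header of unit-carrying column names, e.g.::

    #model=CTM
    #orientation=config1
    t_s	delta_um	force_nN
    0	0	0
    ...

Values are written with 12 significant digits so a write/read round trip is
lossless at that precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .materials import ParameterError

__all__ = ["Curve", "CurveFormatError", "read_curve", "write_curve", "KNOWN_COLUMNS"]

#: Recognised column names (units encoded in the name).
KNOWN_COLUMNS = ("t_s", "force_nN", "delta_um", "Lp_um", "dP_MPa", "Lp_over_Rp", "Lp_over_Rc")

_SIGNALS = ("force_nN", "Lp_um", "Lp_over_Rp", "Lp_over_Rc")
_DRIVERS = ("delta_um", "dP_MPa")


class CurveFormatError(ValueError):
    """A curve file violates the expected delimited-text format."""


@dataclass
class Curve:
    """Columnar curve record with strictly increasing time."""

    t: np.ndarray
    y: np.ndarray
    y_name: str
    driver: Optional[np.ndarray] = None
    driver_name: Optional[str] = None
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.shape != self.t.shape:
            raise ParameterError("t and y must be one-dimensional and equally long")
        if self.driver is not None:
            self.driver = np.asarray(self.driver, dtype=float)
            if self.driver.shape != self.t.shape:
                raise ParameterError("driver column length must match t")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ParameterError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_s": self.t}
        if self.driver is not None:
            cols[self.driver_name] = self.driver
        cols[self.y_name] = self.y
        return pd.DataFrame(cols)

    def plot(self, ax=None):
        """Quick-look plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.y)
        ax.set_xlabel("t (s)")
        ax.set_ylabel(self.y_name)
        return ax


def write_curve(curve: Curve, path) -> None:
    with open(path, "w") as fh:
        for key, val in curve.meta.items():
            fh.write(f"#{key}={val}\n")
        frame = curve.to_frame()
        fh.write("\t".join(frame.columns) + "\n")
        fmt = "\t".join(["%.12g"] * frame.shape[1])
        for row in frame.itertuples(index=False):
            fh.write(fmt % tuple(row) + "\n")


def read_curve(path, decimal: str = ".") -> Curve:
    """Parse a curve TSV; raises :class:`CurveFormatError` (with a line
    number where possible) on unknown columns, non-monotone time or
    locale-mismatched decimal separators."""
    text = Path(path).read_text()
    meta: Dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break

    if body_start >= len(lines):
        raise CurveFormatError(f"{path}: no data table found")
    header = lines[body_start].split("\t")
    unknown = [c for c in header if c not in KNOWN_COLUMNS]
    if unknown:
        raise CurveFormatError(
            f"{path}, line {body_start + 1}: unknown column(s) {unknown}; "
            f"expected names from {KNOWN_COLUMNS}"
        )
    if "t_s" not in header:
        raise CurveFormatError(f"{path}, line {body_start + 1}: missing required column 't_s'")

    body = "\n".join(lines[body_start:])
    if decimal == "." and _looks_european(lines[body_start + 1:]):
        raise CurveFormatError(
            f"{path}: values appear to use ',' as the decimal separator; "
            "re-read with decimal=',' (CLI: --decimal ,)"
        )
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t", decimal=decimal)
    except ValueError as err:
        raise CurveFormatError(f"{path}: could not parse table ({err})") from err
    for col in header:
        if not np.issubdtype(df[col].dtype, np.number):
            raise CurveFormatError(f"{path}: column {col!r} contains non-numeric values")

    t = df["t_s"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        line_no = body_start + 2 + int(bad[0]) + 1  # 1-based, after header
        raise CurveFormatError(f"{path}, line {line_no}: time is not strictly increasing")

    y_name = next((c for c in header if c in _SIGNALS), None)
    if y_name is None:
        raise CurveFormatError(f"{path}: no signal column among {_SIGNALS}")
    driver_name = next((c for c in header if c in _DRIVERS), None)
    return Curve(
        t=t,
        y=df[y_name].to_numpy(dtype=float),
        y_name=y_name,
        driver=None if driver_name is None else df[driver_name].to_numpy(dtype=float),
        driver_name=driver_name,
        meta=meta,
    )


def _looks_european(data_lines) -> bool:
    for line in data_lines[:20]:
        fields = line.split("\t")
        for f in fields:
            if "," in f and "." not in f:
                return True
    return False
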