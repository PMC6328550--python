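"""Localization tables, the canvas model, and on-disk formats.

SMLM data are lists of molecular localization coordinates, not images.  All
analysis in this package runs on continuous coordinates in nanometres on a
bounded rectangular canvas; nothing is ever rendered into pixels except the
Fourier-transform validation oracle.

The interchange format is a plain CSV with header ``x_nm,y_nm,channel`` and
optional ``sigma_nm`` (per-localization precision) and ``frame`` columns.
Comment lines start with ``#``; on write, the canvas extents are embedded as a
comment so files are self-describing.  Coordinates are written with ``repr``
precision and therefore round-trip losslessly.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Canvas",
    "LocalizationSet",
    "read_localizations",
    "write_localizations",
    "LocalizationFormatError",
    "EmptyInputError",
]


class LocalizationFormatError(ValueError):
    """A localization table is malformed (e.g. a required column is missing)."""


class EmptyInputError(ValueError):
    """An input file contains no localizations."""


@dataclass(frozen=True)
class Canvas:
    """Closed rectangular observation window, in nanometres.

    The origin convention is continuous Cartesian: x increases rightward and
    y increases upward from the lower-left corner.  Points exactly on the
    boundary count as inside.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        for name in ("x_min", "x_max", "y_min", "y_max"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate canvas: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def area(self) -> float:
        """Canvas area in nm^2 (the normalization constant A)."""
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed rectangle.

        Parameters
        ----------
        xy : (N, 2) array of coordinates in nm.
        """
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= self.x_min)
            & (xy[..., 0] <= self.x_max)
            & (xy[..., 1] >= self.y_min)
            & (xy[..., 1] <= self.y_max)
        )

    @staticmethod
    def bounding(xy: np.ndarray) -> "Canvas":
        """Tight bounding box of a point set (the "auto" canvas)."""
        xy = np.asarray(xy, dtype=float)
        if xy.size == 0:
            raise EmptyInputError("cannot derive a canvas from zero points")
        x_min, y_min = xy.min(axis=0)
        x_max, y_max = xy.max(axis=0)
        if x_max == x_min:
            x_max = x_min + 1.0
        if y_max == y_min:
            y_max = y_min + 1.0
        return Canvas(x_min, x_max, y_min, y_max)


@dataclass
class LocalizationSet:
    """Localization coordinates of one molecular species (one color channel).

    Attributes
    ----------
    channel : free-form channel label (the analysis roles R/B/G are assigned
        at call time, never stored in the data).
    xy : (N, 2) float64 array of coordinates in nm.
    canvas : the shared observation window.
    sigma : optional (N,) per-localization precision in nm.
    frame : optional (N,) acquisition frame index.
    """

    channel: str
    xy: np.ndarray
    canvas: Canvas
    sigma: Optional[np.ndarray] = None
    frame: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        if self.xy.shape[1] != 2:
            raise ValueError("xy must be an (N, 2) array")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != (len(self.xy),):
                raise ValueError("sigma must be one value per localization")
        if self.frame is not None:
            self.frame = np.asarray(self.frame)

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def n(self) -> int:
        return len(self.xy)

    def density_per_um2(self) -> float:
        """Average density rho = N / A in points per µm²."""
        return self.n / self.canvas.area() * 1e6


def _format_canvas_comment(canvas: Canvas) -> str:
    return (
        f"# canvas: x_min={canvas.x_min!r} x_max={canvas.x_max!r} "
        f"y_min={canvas.y_min!r} y_max={canvas.y_max!r}"
    )


def _parse_canvas_comment(lines: list[str]) -> Optional[Canvas]:
    for line in lines:
        if line.startswith("# canvas:"):
            fields = dict(
                tok.split("=", 1) for tok in line[len("# canvas:"):].split()
            )
            return Canvas(*(float(fields[k]) for k in ("x_min", "x_max", "y_min", "y_max")))
    return None


def read_localizations(
    path: Union[str, Path],
    canvas: Union[Canvas, str] = "auto",
) -> dict[str, LocalizationSet]:
    """Read a localization CSV into one :class:`LocalizationSet` per channel.

    Parameters
    ----------
    path : CSV file with header ``x_nm,y_nm,channel[,sigma_nm,frame]``.
    canvas : how to bound the data:
        * an explicit :class:`Canvas` — points outside are dropped (the count
          is logged),
        * ``"auto"`` — the tight bounding box of all points,
        * ``"embedded"`` — the canvas recorded in the file's ``# canvas:``
          comment (written by :func:`write_localizations`).

    Returns
    -------
    dict mapping each distinct channel label to its localizations, in file
    order within each channel.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]

    try:
        df = pd.read_csv(_stdio.StringIO(text), comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no localizations")
    for col in ("x_nm", "y_nm", "channel"):
        if col not in df.columns:
            raise LocalizationFormatError(f"{path}: missing required column '{col}'")

    xy_all = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if isinstance(canvas, Canvas):
        cv = canvas
        keep = cv.contains(xy_all)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d localizations outside the canvas", path, n_dropped)
        df = df.loc[keep]
    elif canvas == "auto":
        cv = Canvas.bounding(xy_all)
    elif canvas == "embedded":
        cv = _parse_canvas_comment(comment_lines)
        if cv is None:
            raise LocalizationFormatError(f"{path}: no '# canvas:' comment to read")
        keep = cv.contains(xy_all)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d localizations outside the canvas", path, n_dropped)
        df = df.loc[keep]
    else:
        raise ValueError(f"canvas must be a Canvas, 'auto' or 'embedded', got {canvas!r}")

    out: dict[str, LocalizationSet] = {}
    for label, sub in df.groupby("channel", sort=True):
        out[str(label)] = LocalizationSet(
            channel=str(label),
            xy=sub[["x_nm", "y_nm"]].to_numpy(dtype=float),
            canvas=cv,
            sigma=sub["sigma_nm"].to_numpy(dtype=float) if "sigma_nm" in sub else None,
            frame=sub["frame"].to_numpy() if "frame" in sub else None,
        )
    return out


def write_localizations(
    sets: Mapping[str, LocalizationSet],
    path: Union[str, Path],
) -> None:
    """Write localization sets to CSV, deterministically.

    Rows are ordered by channel label (sorted), then input order.  All sets
    must share one canvas, which is embedded as a ``# canvas:`` comment.
    Floats are written with ``repr`` precision, so write/read/write is
    byte-identical and coordinates round-trip exactly.
    """
    path = Path(path)
    sets = dict(sets)
    if not sets:
        raise EmptyInputError("nothing to write")
    canvases = {s.canvas for s in sets.values()}
    if len(canvases) != 1:
        raise ValueError("all localization sets must share one canvas")
    canvas = next(iter(canvases))

    labels = sorted(sets)
    has_sigma = any(s.sigma is not None for s in sets.values())
    has_frame = any(s.frame is not None for s in sets.values())

    frames = []
    for label in labels:
        s = sets[label]
        d = {"x_nm": s.xy[:, 0], "y_nm": s.xy[:, 1], "channel": s.channel}
        if has_sigma:
            d["sigma_nm"] = s.sigma if s.sigma is not None else np.full(s.n, np.nan)
        if has_frame:
            d["frame"] = s.frame if s.frame is not None else np.full(s.n, -1)
        frames.append(pd.DataFrame(d))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_format_canvas_comment(canvas) + "\n")
        cols = ["x_nm", "y_nm", "channel"]
        if has_sigma:
            cols.append("sigma_nm")
        if has_frame:
            cols.append("frame")
        if df.empty:
            fh.write(",".join(cols) + "\n")
        else:
            df.to_csv(fh, index=False, columns=cols)
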