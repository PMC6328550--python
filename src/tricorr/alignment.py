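"""Second-order polynomial registration of one color channel onto a reference.

Chromatic aberration shifts localizations between color channels by a smooth,
slowly varying field.  It is modelled here, per channel pair, by a full
second-order bivariate polynomial with nine coefficients per output axis:

    x_ref = sum_{j=0}^{8} Kx_j * x_src^l * y_src^m,   l = j // 3,  m = j % 3

and likewise for y_ref.  The coefficients are fitted by ordinary least squares
from matched fiducial bead positions imaged in both channels.  Only second
order is exposed: higher orders overfit typical bead layouts.

Raw second-order monomials on ~1e4-nm coordinates give condition numbers
around 1e16, so the solve runs internally on coordinates centered and scaled
to an O(1) box; the returned coefficients are re-expanded into the raw
monomial basis above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "PolynomialMap",
    "fit_polynomial_map",
    "apply_polynomial_map",
    "UnderdeterminedError",
    "ConditioningError",
]

N_TERMS = 9  # fixed: full 2nd-order bivariate basis


class UnderdeterminedError(ValueError):
    """Fewer bead pairs than coefficients."""


class ConditioningError(ValueError):
    """Bead layout does not determine the polynomial (e.g. collinear beads)."""


def _monomials(xy: np.ndarray) -> np.ndarray:
    """Design matrix: column j is x^(j//3) * y^(j%3)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x, y = xy[:, 0], xy[:, 1]
    cols = [x ** (j // 3) * y ** (j % 3) for j in range(N_TERMS)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class PolynomialMap:
    """Fitted second-order map from ``source`` channel onto ``reference``.

    ``kx`` and ``ky`` are the nine coefficients per axis in the raw monomial
    basis (ordering ``j -> x^(j//3) y^(j%3)``).
    """

    kx: np.ndarray
    ky: np.ndarray
    source: str = "src"
    reference: str = "ref"
    rms_residual_nm: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kx", np.asarray(self.kx, dtype=float))
        object.__setattr__(self, "ky", np.asarray(self.ky, dtype=float))
        if self.kx.shape != (N_TERMS,) or self.ky.shape != (N_TERMS,):
            raise ValueError(f"exactly {N_TERMS} coefficients per axis required")

    @staticmethod
    def identity(source: str = "src", reference: str = "ref") -> "PolynomialMap":
        kx = np.zeros(N_TERMS)
        ky = np.zeros(N_TERMS)
        kx[3] = 1.0  # j=3 -> l=1, m=0 -> x
        ky[1] = 1.0  # j=1 -> l=0, m=1 -> y
        return PolynomialMap(kx, ky, source, reference, rms_residual_nm=0.0)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        return apply_polynomial_map(self, xy)

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "reference": self.reference,
                "kx": self.kx.tolist(),
                "ky": self.ky.tolist(),
                "rms_residual_nm": self.rms_residual_nm,
                "basis": "j -> x^(j//3) * y^(j%3), j = 0..8",
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "PolynomialMap":
        doc = json.loads(text)
        return PolynomialMap(
            kx=np.array(doc["kx"], dtype=float),
            ky=np.array(doc["ky"], dtype=float),
            source=doc.get("source", "src"),
            reference=doc.get("reference", "ref"),
            rms_residual_nm=doc.get("rms_residual_nm"),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @staticmethod
    def load(path: Union[str, Path]) -> "PolynomialMap":
        return PolynomialMap.from_json(Path(path).read_text(encoding="utf-8"))


def _rescale_coeffs(k_scaled: np.ndarray, cx: float, cy: float, s: float) -> np.ndarray:
    """Re-expand coefficients fitted on u=(x-cx)/s, v=(y-cy)/s into raw x, y."""
    k_raw = np.zeros((3, 3))
    for j in range(N_TERMS):
        l, m = j // 3, j % 3
        c = k_scaled[j]
        if c == 0.0:
            continue
        # (x-cx)^l / s^l  expands over x^a, analogously for y
        for a in range(l + 1):
            ca = comb(l, a) * (-cx) ** (l - a) / s**l
            for b in range(m + 1):
                cb = comb(m, b) * (-cy) ** (m - b) / s**m
                k_raw[a, b] += c * ca * cb
    return np.array([k_raw[j // 3, j % 3] for j in range(N_TERMS)])


def fit_polynomial_map(
    ref_points: np.ndarray,
    src_points: np.ndarray,
    source: str = "src",
    reference: str = "ref",
) -> PolynomialMap:
    """Least-squares fit of the second-order map ``src -> ref``.

    Parameters
    ----------
    ref_points, src_points : (N, 2) arrays of matched bead positions in nm
        (the i-th row of each is the same physical bead seen in the two
        channels).  At least 9 pairs in general position are required.

    Returns
    -------
    :class:`PolynomialMap` with coefficients in the raw monomial basis and
    the RMS residual (nm) over the fitting beads.
    """
    ref = np.atleast_2d(np.asarray(ref_points, dtype=float))
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    if ref.shape != src.shape or ref.shape[1] != 2:
        raise ValueError("ref_points and src_points must be matching (N, 2) arrays")
    n = len(src)
    if n < N_TERMS:
        raise UnderdeterminedError(f"need >= {N_TERMS} bead pairs, got {n}")

    cx, cy = src.mean(axis=0)
    s = float(np.abs(src - [cx, cy]).max())
    if s == 0.0:
        raise ConditioningError("all source beads coincide")
    uv = (src - [cx, cy]) / s
    design = _monomials(uv)
    rank = np.linalg.matrix_rank(design)
    if rank < N_TERMS:
        raise ConditioningError(
            f"bead layout is rank-deficient (rank {rank} < {N_TERMS}); "
            "beads may be collinear or too few distinct positions"
        )
    kx_s, *_ = np.linalg.lstsq(design, ref[:, 0], rcond=None)
    ky_s, *_ = np.linalg.lstsq(design, ref[:, 1], rcond=None)

    pred = np.column_stack([design @ kx_s, design @ ky_s])
    rms = float(np.sqrt(np.mean(np.sum((pred - ref) ** 2, axis=1))))

    kx = _rescale_coeffs(kx_s, cx, cy, s)
    ky = _rescale_coeffs(ky_s, cx, cy, s)
    return PolynomialMap(kx, ky, source, reference, rms_residual_nm=rms)


def apply_polynomial_map(pmap: PolynomialMap, xy: np.ndarray) -> np.ndarray:
    """Transform ``(N, 2)`` source-channel coordinates onto the reference."""
    design = _monomials(xy)
    return np.column_stack([design @ pmap.kx, design @ pmap.ky])
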