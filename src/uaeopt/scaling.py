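"""Reversible column-wise scaling.

Two kinds are supported: min-max scaling onto a target interval (used to
bring factors and responses into the working range of the network
activations) and z-scoring (used for standardized PCA and for the
standard-score sample ranking).  Both are affine per column, so the inverse
transform is exact, and values outside the fitted range are extrapolated
linearly rather than clipped — optimization is allowed to probe the edges
of the design box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Scaler", "fit_scaler"]


@dataclass
class Scaler:
    """Per-column affine transform ``y = a * x + b`` with exact inverse.

    Parameters are stored per column.  Constant columns get ``a = 0`` with a
    declared policy: min-max maps them to the midpoint of the target
    interval, z-score maps them to 0; the inverse returns the original
    constant in either case.
    """

    kind: str                      # "minmax" | "zscore"
    a: np.ndarray
    b: np.ndarray
    data_min: np.ndarray
    data_max: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    interval: tuple[float, float] = (0.0, 1.0)
    ddof: int = 1
    constant: np.ndarray = field(default=None)

    @property
    def n_columns(self) -> int:
        return self.a.size

    def _check(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim == 1:
            matrix = matrix[:, None]
        if matrix.shape[1] != self.n_columns:
            raise ValueError(
                f"column mismatch: scaler was fitted on {self.n_columns} "
                f"column(s), got {matrix.shape[1]}"
            )
        return matrix

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        matrix = self._check(matrix)
        return matrix * self.a + self.b

    def invert(self, matrix: np.ndarray) -> np.ndarray:
        matrix = self._check(matrix)
        out = np.empty_like(matrix)
        const = self.constant
        safe = ~const
        out[:, safe] = (matrix[:, safe] - self.b[safe]) / self.a[safe]
        # constant columns: any scaled value maps back to the fitted constant
        out[:, const] = self.data_min[const]
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "interval": list(self.interval),
            "ddof": self.ddof,
            "data_min": self.data_min.tolist(),
            "data_max": self.data_max.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Scaler":
        return fit_scaler_from_stats(
            kind=doc["kind"],
            data_min=np.asarray(doc["data_min"], dtype=float),
            data_max=np.asarray(doc["data_max"], dtype=float),
            mean=np.asarray(doc["mean"], dtype=float),
            sd=np.asarray(doc["sd"], dtype=float),
            interval=tuple(doc.get("interval", (0.0, 1.0))),
            ddof=int(doc.get("ddof", 1)),
        )


def fit_scaler_from_stats(kind, data_min, data_max, mean, sd,
                          interval=(0.0, 1.0), ddof=1) -> Scaler:
    lo, hi = interval
    if not hi > lo:
        raise ValueError("target interval must satisfy hi > lo")
    if kind == "minmax":
        span = data_max - data_min
        const = span == 0
        a = np.where(const, 0.0, (hi - lo) / np.where(const, 1.0, span))
        b = np.where(const, 0.5 * (lo + hi), lo - data_min * a)
    elif kind == "zscore":
        const = sd == 0
        a = np.where(const, 0.0, 1.0 / np.where(const, 1.0, sd))
        b = np.where(const, 0.0, -mean * a)
    else:
        raise ValueError(f"unknown scaler kind {kind!r}")
    return Scaler(kind=kind, a=a, b=b, data_min=data_min, data_max=data_max,
                  mean=mean, sd=sd, interval=(lo, hi), ddof=ddof,
                  constant=const)


def fit_scaler(matrix: np.ndarray, kind: str = "minmax",
               interval: tuple[float, float] = (0.0, 1.0),
               ddof: int = 1) -> Scaler:
    """Fit a reversible per-column scaler.

    Parameters
    ----------
    matrix
        2-D array (observations x variables); a 1-D array is treated as a
        single column.
    kind
        ``"minmax"`` maps the observed [min, max] of every column onto
        `interval`; ``"zscore"`` centres and scales to unit SD.
    interval
        Target interval for min-max scaling (ignored for z-scoring).
    ddof
        Delta degrees of freedom for the z-score SD (1 = sample SD).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    if matrix.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    sd = matrix.std(axis=0, ddof=ddof) if matrix.shape[0] > ddof else \
        np.zeros(matrix.shape[1])
    scaler = fit_scaler_from_stats(
        kind, matrix.min(axis=0), matrix.max(axis=0),
        matrix.mean(axis=0), sd, interval=interval, ddof=ddof)
    if kind == "zscore" and scaler.constant.any():
        cols = np.flatnonzero(scaler.constant).tolist()
        warnings.warn(f"constant column(s) {cols} z-scored to 0", stacklevel=2)
    return scaler
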