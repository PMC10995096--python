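"""The weighted indicator system: AHP, min-max normalization, the
landscape-quality composite index (LQCI), and level classification.

The composite index for year *i* is the weighted sum

    LQCI_i = sum_j w_j * V_ij

with weights ``w_j`` in percent as printed in the packaged indicator table
and ``V_ij`` the min-max normalized indicator values in [0, 1].  Because the
packaged weights sum to ~55.9 % (they are used exactly as printed, without
renormalization), LQCI ranges over [0, ~55.9], which is the only reading
consistent with the published truth series (28.77-43.72).

A score *x* is mapped to one of ``n`` ordered quality levels on a scale
``[s1, sn]`` by ``k = ceil((x - s1)/(sn - s1) * n)`` clamped to [1, n],
with ``k = n`` the best level (roman I) and ``k = 1`` the worst (IV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, isfinite

import numpy as np
import pandas as pd

__all__ = [
    "LevelScale",
    "NormalizedMatrix",
    "ahp_weights",
    "normalize",
    "denormalize",
    "compute_lqci",
    "lqci_series",
    "assign_level",
    "RANDOM_INDEX",
]

# Saaty's random consistency index by matrix order (1-based; RI[n]).
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54,
                13: 1.56, 14: 1.57, 15: 1.59}


def ahp_weights(pairwise: np.ndarray, *, reciprocal_rtol: float = 1e-6
                ) -> tuple[np.ndarray, float]:
    """Analytic-hierarchy-process weights from a pairwise comparison matrix.

    Returns ``(weights, consistency_ratio)`` where weights is the normalized
    principal right eigenvector (sums to 1) and
    ``CR = ((lambda_max - n)/(n - 1)) / RI(n)``.  ``CR <= 0.1`` is the
    conventional acceptance threshold; this function only reports CR.

    Raises ``ValueError`` for n < 2 or a matrix that is not positive and
    reciprocal (``a_ji = 1/a_ij``, unit diagonal).
    """
    a = np.asarray(pairwise, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("pairwise matrix must be square")
    n = a.shape[0]
    if n < 2:
        raise ValueError("pairwise matrix must be at least 2x2")
    if np.any(a <= 0):
        raise ValueError("pairwise matrix must be strictly positive")
    if not np.allclose(a * a.T, 1.0, rtol=reciprocal_rtol):
        raise ValueError("pairwise matrix must be reciprocal (a_ji = 1/a_ij)")
    eigvals, eigvecs = np.linalg.eig(a)
    k = int(np.argmax(eigvals.real))
    lam = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX.get(n)
    if ri is None:
        raise ValueError(f"no random-index entry for n={n}")
    cr = 0.0 if ri == 0 else ci / ri
    return w, cr


@dataclass
class NormalizedMatrix:
    """Years x indicators matrix of V_ij in [0, 1] plus column statistics.

    ``constant_columns`` lists indicators whose raw column was constant;
    those are set to 0.5 everywhere and flagged rather than dropped.
    ``col_min``/``col_max`` are the raw per-column extrema used, kept so
    the scaling can be inverted or re-applied to new rows.
    """

    v: pd.DataFrame
    polarity: dict[str, str]
    col_min: pd.Series
    col_max: pd.Series
    constant_columns: list[str] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.v.index]


def normalize(raw: pd.DataFrame, polarity: dict[str, str] | str = "benefit"
              ) -> NormalizedMatrix:
    """Min-max normalize each indicator column to [0, 1].

    benefit: ``(x - min)/(max - min)``; cost: ``(max - x)/(max - min)``.
    ``polarity`` is either a single direction applied to every column or a
    per-column mapping (missing keys default to benefit).  A constant column
    maps to 0.5 everywhere and is flagged; an all-missing column is an error.
    """
    if isinstance(polarity, str):
        pol = {c: polarity for c in raw.columns}
    else:
        pol = {c: polarity.get(c, "benefit") for c in raw.columns}
    bad = [p for p in pol.values() if p not in ("benefit", "cost")]
    if bad:
        raise ValueError(f"unknown polarity {bad[0]!r}")
    v = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    constant = []
    col_min, col_max = {}, {}
    for c in raw.columns:
        x = raw[c].astype(float)
        if x.notna().sum() < 1:
            raise ValueError(f"column {c!r} has no finite values")
        lo, hi = float(x.min()), float(x.max())
        col_min[c], col_max[c] = lo, hi
        if hi == lo:
            v[c] = 0.5
            constant.append(c)
            continue
        scaled = (x - lo) / (hi - lo)
        v[c] = 1.0 - scaled if pol[c] == "cost" else scaled
    return NormalizedMatrix(v=v, polarity=pol,
                            col_min=pd.Series(col_min), col_max=pd.Series(col_max),
                            constant_columns=constant)


def denormalize(norm: NormalizedMatrix) -> pd.DataFrame:
    """Invert :func:`normalize` (identity on non-constant columns)."""
    raw = pd.DataFrame(index=norm.v.index, columns=norm.v.columns, dtype=float)
    for c in norm.v.columns:
        lo, hi = norm.col_min[c], norm.col_max[c]
        if hi == lo:
            raw[c] = lo
            continue
        x = norm.v[c]
        if norm.polarity[c] == "cost":
            x = 1.0 - x
        raw[c] = lo + x * (hi - lo)
    return raw


def compute_lqci(v_row, weights) -> float:
    """Weighted composite index for one year: ``sum_j w_j * V_ij``.

    ``weights`` are in percent as printed; with all V in [0, 1] the maximum
    attainable score is ``sum(weights)``.
    """
    v = np.asarray(v_row, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("v_row and weights must be aligned 1-D vectors")
    if np.any((v < -1e-12) | (v > 1 + 1e-12)):
        raise ValueError("normalized values must lie in [0, 1]")
    return float(w @ v)


def lqci_series(norm: NormalizedMatrix, weights: dict[str, float] | np.ndarray
                ) -> pd.Series:
    """LQCI for every year of a normalized matrix."""
    if isinstance(weights, dict):
        w = np.array([weights[c] for c in norm.v.columns], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    return pd.Series(norm.v.to_numpy() @ w, index=norm.v.index, name="lqci")


@dataclass(frozen=True)
class LevelScale:
    """Score scale for level classification.

    ``labels`` are ordered best-first; with the default four roman labels,
    ordinal ``k = n`` maps to "I" (best) and ``k = 1`` to "IV" (worst).
    """

    s1: float
    sn: float
    n_levels: int = 4
    labels: tuple[str, ...] = ("I", "II", "III", "IV")

    def __post_init__(self) -> None:
        if not (self.sn > self.s1):
            raise ValueError("sn must be greater than s1")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        if len(self.labels) != self.n_levels:
            raise ValueError("labels length must equal n_levels")


def assign_level(x: float, scale: LevelScale) -> str:
    """Map a composite score to its quality level via ceil rounding.

    ``k = ceil((x - s1)/(sn - s1) * n)`` clamped to [1, n]; the best label
    is returned for ``k = n``.  Scores at or below ``s1`` clamp to the worst
    level, at or above ``sn`` to the best.
    """
    if not isfinite(x):
        raise ValueError("score must be finite")
    n = scale.n_levels
    k = ceil((x - scale.s1) / (scale.sn - scale.s1) * n)
    k = min(max(k, 1), n)
    return scale.labels[n - k]
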