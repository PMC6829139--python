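"""Two-point linkage for phase-unknown haploid data, and map functions.

For a pair of biallelic loci scored on the same gametes, the observable is
the mismatch count d among the n gametes non-missing at both loci.  Because
the parental phase is unknown, the recombination fraction is estimated
phase-minimised: k = min(d, n - d), r_hat = k / n.  The LOD score is the
base-10 log likelihood ratio of linkage at r_hat versus free recombination
(r = 1/2):

    LOD = (n - k) * log10(2 * (1 - r_hat)) + k * log10(2 * r_hat)

with the convention 0 * log10(0) = 0, so identical columns give
LOD = n * log10(2) and d = n/2 gives LOD = 0.

Map distances use the Kosambi function d_cM = 25 * ln((1+2r)/(1-2r)) and its
inverse r = tanh(d_cM / 50) / 2, which allows for moderate crossover
interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_R = 0.4       # r assigned to uninformative pairs
DEFAULT_R_CAP = 0.4999  # max r before Kosambi conversion (keeps cM finite)


@dataclass(frozen=True)
class MapFunctionParams:
    """Map-function and uninformative-pair conventions."""
    function: str = "kosambi"          # kosambi | haldane
    r_cap: float = DEFAULT_R_CAP
    default_r: float = DEFAULT_R

    def __post_init__(self):
        if not 0.0 < self.r_cap < 0.5:
            raise ValueError("r_cap must lie in (0, 0.5)")
        if self.function not in ("kosambi", "haldane"):
            raise ValueError(f"unknown map function {self.function!r}")


def kosambi(r, r_cap: float = DEFAULT_R_CAP):
    """Kosambi map distance in cM for recombination fraction r.

    r at or above 0.5 is clipped to ``r_cap`` with a warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    if np.any(r >= 0.5):
        warnings.warn(f"recombination fraction >= 0.5 clipped to {r_cap}",
                      stacklevel=2)
        r = np.minimum(r, r_cap)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cM):
    """Recombination fraction for a Kosambi map distance in cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane(r, r_cap: float = DEFAULT_R_CAP):
    """Haldane (no-interference) map distance in cM."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= 0.5):
        warnings.warn(f"recombination fraction >= 0.5 clipped to {r_cap}",
                      stacklevel=2)
        r = np.minimum(r, r_cap)
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def map_distance(r, params: MapFunctionParams = MapFunctionParams()):
    fn = kosambi if params.function == "kosambi" else haldane
    return fn(r, r_cap=params.r_cap)


@dataclass(frozen=True)
class TwoPointEstimate:
    """Phase-minimised two-point estimate for one marker pair."""
    r_hat: float
    lod: float
    n_informative: int
    phase_flipped: bool
    informative: bool = True


def _lod_from_counts(k, n):
    """LOD of r_hat=k/n vs r=0.5 with 0*log10(0) = 0 (vectorised)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.5)
        t1 = np.where(n - k > 0, (n - k) * np.log10(2.0 * (1.0 - r)), 0.0)
        t2 = np.where(k > 0, k * np.log10(2.0 * r), 0.0)
    return t1 + t2


def estimate_two_point(x, y, default_r: float = DEFAULT_R,
                       n_min: int = 1) -> TwoPointEstimate:
    """Two-point recombination fraction and LOD for two loci.

    Parameters
    ----------
    x, y : array-like of int8
        Allele calls coded 0/1 with -1 for missing.  The 0/1 labelling per
        locus is arbitrary; the estimate is phase-minimised.
    default_r : float
        r reported for uninformative pairs (fewer than ``n_min`` shared
        non-missing gametes).
    n_min : int
        Minimum shared non-missing gametes for the pair to be informative.
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError("loci scored on different numbers of gametes")
    bad = ((x > 1) | (x < -1) | (y > 1) | (y < -1))
    if np.any(bad):
        raise ValueError("input is not 0/1/-1 coded (non-biallelic locus?)")
    shared = (x >= 0) & (y >= 0)
    n = int(shared.sum())
    if n < max(n_min, 1):
        return TwoPointEstimate(r_hat=default_r, lod=0.0, n_informative=n,
                                phase_flipped=False, informative=False)
    d = int(np.count_nonzero(x[shared] != y[shared]))
    k = min(d, n - d)
    lod = float(_lod_from_counts(k, n))
    return TwoPointEstimate(r_hat=k / n, lod=max(lod, 0.0), n_informative=n,
                            phase_flipped=d > n - d)


@dataclass
class PairwiseLODMatrix:
    """Symmetric pairwise two-point estimates over a marker set.

    Stored dense; intended for use on co-segregation bin representatives
    where the marker count is modest.  The diagonal is undefined and set to
    r = 0, LOD = 0 by convention.
    """
    ids: pd.Index
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray
    phase_flipped: np.ndarray
    informative: np.ndarray = field(repr=False, default=None)

    def lod_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lod, index=self.ids, columns=self.ids)

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


def pairwise_two_point(X: np.ndarray, ids=None, default_r: float = DEFAULT_R,
                       n_min: int = 20) -> PairwiseLODMatrix:
    """All-pairs two-point estimates for an encoded 0/1/-1 matrix.

    Vectorised via matrix products on the valid-call indicator: for loci i, j
    the shared informative count is n_ij = M M^T and the mismatch count is
    d_ij = A (M-A)^T + (M-A) A^T where A marks valid 1-alleles.
    """
    X = np.asarray(X, dtype=np.int8)
    m = X.shape[0]
    if ids is None:
        ids = pd.RangeIndex(m)
    ids = pd.Index(ids)
    M = (X >= 0).astype(np.float64)
    A = (X == 1).astype(np.float64)
    B = M - A
    n = M @ M.T
    d = A @ B.T + B @ A.T
    k = np.minimum(d, n - d)
    informative = n >= max(n_min, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(informative, k / np.maximum(n, 1), default_r)
    lod = np.where(informative, _lod_from_counts(k, n), 0.0)
    lod = np.maximum(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return PairwiseLODMatrix(ids=ids, r=r, lod=lod,
                             n=n.astype(np.int64),
                             phase_flipped=d > (n - d),
                             informative=informative)
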