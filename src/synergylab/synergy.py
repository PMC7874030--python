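"""Muscle-synergy extraction and spatiotemporal primitive metrics.

The muscles-by-time envelope matrix V is factorized as V ~ V_R = W H with
W (m x r) the non-negative motor modules (time-invariant muscle weightings)
and H (r x n) the non-negative motor primitives (time-dependent activation
coefficients), using the classical Gaussian non-negative matrix factorization
with multiplicative updates:

    H <- H * (W^T V) / (W^T W H)
    W <- W * (V H^T) / (W H H^T)

Reconstruction quality is R^2 = 1 - ||V - WH||_F^2 / ||V - mean(V)||_F^2;
iteration stops when the relative change of R^2 over the last 20 iterations
falls below 0.01%. Each rank is fitted from 10 random restarts and the
highest-R^2 solution kept. The model order is chosen from the R^2-vs-rank
curve over ranks 1..round(0.75 m): a straight line is fitted, and the
lowest-rank point is dropped repeatedly until the fit MSE falls below 1e-5
(or two points remain); the chosen rank is the smallest one left.

Primitives are summarized by their center of activity (CoA) - the angle of
the resultant vector of the primitive treated as a circular mass
distribution over the cycle - and their full width at half maximum (FWHM),
the number of normalized time points above half of the minimum-subtracted
maximum. Primitives are clustered by shape across trials; single-peaked
clusters are fundamental synergies, ordered in time as swing, touchdown,
weight acceptance and stabilization, everything else is combined.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .emg import CYCLE_POINTS, EnvelopeMatrix

logger = logging.getLogger(__name__)

EPS = 1e-12

#: Functional labels of fundamental synergies in temporal (CoA) order.
FUNDAMENTAL_LABELS = ("swing", "touchdown", "weight_acceptance", "stabilization")
COMBINED = "combined"


def candidate_ranks(n_muscles: int) -> range:
    """Model-order search space: 1 .. round(0.75 * n_muscles)."""
    if n_muscles < 2:
        raise ValueError("need at least 2 muscles")
    return range(1, int(math.floor(0.75 * n_muscles + 0.5)) + 1)


def reconstruction_r2(v: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    resid = v - w @ h
    total = v - v.mean()
    denom = float(np.sum(total * total))
    if denom <= 0:
        raise ValueError("V has zero total variance; R^2 undefined")
    return 1.0 - float(np.sum(resid * resid)) / denom


def multiplicative_update_step(v: np.ndarray, w: np.ndarray, h: np.ndarray,
                               update_w: bool = True
                               ) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update: H first, then (optionally) W.

    Denominators are epsilon-guarded; both factors stay non-negative and the
    Frobenius reconstruction error is non-increasing.
    """
    h = h * (w.T @ v) / (w.T @ w @ h + EPS)
    if update_w:
        w = w * (v @ h.T) / (w @ h @ h.T + EPS)
    return w, h


def _validate_v(v) -> np.ndarray:
    if isinstance(v, EnvelopeMatrix):
        v = v.values
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("V must be a 2-D muscles-by-time matrix")
    if np.any(v < 0):
        raise ValueError("V must be non-negative")
    if np.any(v.max(axis=1) <= 0):
        dead = list(np.flatnonzero(v.max(axis=1) <= 0))
        raise ValueError(f"V has all-zero rows at indices {dead}")
    return v


@dataclass
class SynergyDecomposition:
    """Best-of-restarts NMF solution at one rank."""

    w: np.ndarray  # (m, r) motor modules
    h: np.ndarray  # (r, n) motor primitives
    rank: int
    r2: float
    restart_r2: list[float]
    seed: int
    n_iter: int
    converged: bool
    r2_history: np.ndarray = field(repr=False, default=None)

    def mean_primitives(self, cycle_points: int = CYCLE_POINTS) -> np.ndarray:
        """(r, 200) mean cycle of each primitive over the concatenated cycles."""
        r, n = self.h.shape
        if n % cycle_points:
            raise ValueError("primitive length is not a whole number of cycles")
        return self.h.reshape(r, n // cycle_points, cycle_points).mean(axis=1)


class SynergyNMF(BaseEstimator, TransformerMixin):
    """Gaussian NMF muscle-synergy extractor (scikit-learn estimator).

    Parameters
    ----------
    n_synergies : int or None
        Factorization rank. None triggers the model-order search over ranks
        1..round(0.75 m) with the linear-fit MSE < 1e-5 dropping rule.
    n_restarts : int
        Random restarts per rank; the highest-R^2 solution is kept.
    tol : float
        Relative R^2 change over ``window`` iterations below which a restart
        is converged (0.0001 = 0.01%).
    window : int
        Convergence window in iterations.
    max_iter : int
        Iteration cap per restart (a warning is emitted on hitting it).
    mse_threshold : float
        Linear-fit MSE threshold of the rank-selection rule.
    random_state : int or None
        Master seed; restart k at rank r uses seed ``random_state + k``.

    Attributes
    ----------
    modules_ : (m, r) non-negative motor-module matrix W, columns scaled so
        the matching primitive has unit maximum.
    primitives_ : (r, n) non-negative motor-primitive matrix H, rows scaled
        to unit maximum (scale folded into W; W H is unchanged).
    rank_ : chosen/requested number of synergies.
    r2_ : reconstruction R^2 of the stored solution.
    r2_curve_ : dict rank -> best R^2 (only after a model-order search).
    decomposition_ : SynergyDecomposition of the stored solution.
    """

    def __init__(self, n_synergies: int | None = None, n_restarts: int = 10,
                 tol: float = 1e-4, window: int = 20, max_iter: int = 10_000,
                 mse_threshold: float = 1e-5, random_state: int | None = None):
        self.n_synergies = n_synergies
        self.n_restarts = n_restarts
        self.tol = tol
        self.window = window
        self.max_iter = max_iter
        self.mse_threshold = mse_threshold
        self.random_state = random_state

    # -- single restart -----------------------------------------------------
    def _fit_single(self, v: np.ndarray, rank: int, seed: int):
        rng = np.random.default_rng(seed)
        m, n = v.shape
        w = rng.uniform(size=(m, rank))
        h = rng.uniform(size=(rank, n))
        history = np.empty(self.max_iter)
        converged = False
        it = 0
        for it in range(self.max_iter):
            w, h = multiplicative_update_step(v, w, h)
            history[it] = reconstruction_r2(v, w, h)
            if it >= self.window:
                prev = history[it - self.window]
                if abs(history[it] - prev) < self.tol * abs(prev):
                    converged = True
                    break
        if not converged:
            warnings.warn(f"NMF rank {rank} hit the iteration cap "
                          f"({self.max_iter}) without converging")
        return w, h, history[: it + 1], converged

    def _fit_rank(self, v: np.ndarray, rank: int, seed: int
                  ) -> SynergyDecomposition:
        best = None
        restart_r2 = []
        for k in range(self.n_restarts):
            w, h, hist, conv = self._fit_single(v, rank, seed + k)
            r2 = hist[-1]
            restart_r2.append(float(r2))
            if best is None or r2 > best[2]:
                best = (w, h, r2, hist, conv)
        w, h, r2, hist, conv = best
        return SynergyDecomposition(w=w, h=h, rank=rank, r2=float(r2),
                                    restart_r2=restart_r2, seed=seed,
                                    n_iter=len(hist), converged=conv,
                                    r2_history=hist)

    # -- estimator interface ------------------------------------------------
    def fit(self, X, y=None):
        v = _validate_v(X)
        reconstruction_r2(v, np.zeros((v.shape[0], 1)), np.zeros((1, v.shape[1])))
        seed = 0 if self.random_state is None else int(self.random_state)
        ranks = candidate_ranks(v.shape[0])
        if self.n_synergies is not None:
            if self.n_synergies not in ranks:
                raise ValueError(
                    f"n_synergies must lie in {ranks} for {v.shape[0]} muscles")
            dec = self._fit_rank(v, self.n_synergies, seed)
            self.r2_curve_ = None
        else:
            curve: dict[int, SynergyDecomposition] = {}
            for r in ranks:
                curve[r] = self._fit_rank(v, r, seed)
            chosen = select_rank_from_curve(
                {r: d.r2 for r, d in curve.items()}, self.mse_threshold)
            dec = curve[chosen]
            self.r2_curve_ = {r: d.r2 for r, d in curve.items()}
        dec = normalize_decomposition(dec)
        self.decomposition_ = dec
        self.modules_ = dec.w
        self.primitives_ = dec.h
        self.rank_ = dec.rank
        self.r2_ = dec.r2
        self.n_iter_ = dec.n_iter
        return self

    def transform(self, X):
        """Project new envelope data onto the fitted modules (solve for H)."""
        check_is_fitted(self, "modules_")
        v = _validate_v(X)
        w = self.modules_
        rng = np.random.default_rng(self.random_state)
        h = rng.uniform(size=(w.shape[1], v.shape[1]))
        prev = None
        for it in range(self.max_iter):
            h = h * (w.T @ v) / (w.T @ w @ h + EPS)
            if it % self.window == self.window - 1:
                r2 = reconstruction_r2(v, w, h)
                if prev is not None and abs(r2 - prev) < self.tol * abs(prev):
                    break
                prev = r2
        return h

    def fit_transform(self, X, y=None):
        return self.fit(X).primitives_


def normalize_decomposition(dec: SynergyDecomposition) -> SynergyDecomposition:
    """Scale each primitive row to unit maximum, folding the scale into W.

    W H is unchanged (the scale indeterminacy of NMF); metrics are computed
    on this fixed normalization.
    """
    scale = dec.h.max(axis=1)
    scale[scale <= 0] = 1.0
    dec.h = dec.h / scale[:, None]
    dec.w = dec.w * scale[None, :]
    return dec


def nmf(v, rank: int, seed: int, **kwargs) -> SynergyDecomposition:
    """Best-of-restarts NMF at a single rank (functional wrapper)."""
    est = SynergyNMF(n_synergies=rank, random_state=seed, **kwargs)
    est.fit(v)
    return est.decomposition_


def select_rank_from_curve(r2_curve: dict[int, float],
                           mse_threshold: float = 1e-5) -> int:
    """Apply the linear-fit dropping rule to an R^2-vs-rank curve."""
    ranks = sorted(r2_curve)
    pts = [(r, r2_curve[r]) for r in ranks]
    while True:
        x = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
        coef = np.polyfit(x, y, 1)
        mse = float(np.mean((np.polyval(coef, x) - y) ** 2))
        if mse < mse_threshold or len(pts) <= 2:
            return pts[0][0]
        pts = pts[1:]


def select_rank(v, seed: int, **kwargs) -> tuple[int, dict[int, float]]:
    """Run the full model-order search; returns (rank, R^2-vs-rank curve)."""
    est = SynergyNMF(n_synergies=None, random_state=seed, **kwargs)
    est.fit(v)
    return est.rank_, est.r2_curve_


# ---------------------------------------------------------------------------
# Spatiotemporal metrics
# ---------------------------------------------------------------------------

def compute_coa(primitive: np.ndarray, tol: float = 1e-9) -> float:
    """Center of activity of a primitive, in cycle points [0, n).

    The cycle is mapped onto the unit circle (theta_t = 2 pi (t-1)/n for
    t = 1..n), the primitive is treated as a mass distribution, and the CoA
    is the quadrant-aware angle of the resultant (A, B) with
    A = sum cos(theta_t) H_t and B = sum sin(theta_t) H_t, mapped back to
    points as n * angle / (2 pi).
    """
    h = np.asarray(primitive, dtype=float)
    if h.ndim != 1 or h.size == 0:
        raise ValueError("primitive must be a non-empty vector")
    if np.any(h < 0):
        raise ValueError("primitive must be non-negative")
    total = h.sum()
    if total <= 0:
        raise ValueError("primitive is all zero; CoA undefined")
    n = h.size
    theta = 2 * np.pi * np.arange(n) / n
    a = float(np.sum(np.cos(theta) * h))
    b = float(np.sum(np.sin(theta) * h))
    if np.hypot(a, b) < tol * total:
        raise ValueError("resultant vector is (numerically) zero; "
                         "CoA undefined for a uniform primitive")
    angle = math.atan2(b, a) % (2 * np.pi)
    return n * angle / (2 * np.pi)


def compute_fwhm(primitive: np.ndarray) -> int:
    """Full width at half maximum: number of points strictly above half of
    the minimum-subtracted maximum."""
    h = np.asarray(primitive, dtype=float)
    if h.ndim != 1 or h.size == 0:
        raise ValueError("primitive must be a non-empty vector")
    if np.any(h < 0):
        raise ValueError("primitive must be non-negative")
    h = h - h.min()
    peak = h.max()
    if peak <= 0:
        raise ValueError("constant primitive; FWHM undefined")
    return int(np.sum(h > peak / 2))


def count_peaks(primitive: np.ndarray, smooth: int = 5) -> int:
    """Number of local maxima above half maximum of the (lightly smoothed,
    minimum-subtracted) primitive; boundary maxima count."""
    h = np.asarray(primitive, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        h = np.convolve(np.pad(h, pad, mode="edge"), kernel, mode="same")[
            pad:len(h) + pad]
    h = h - h.min()
    half = h.max() / 2
    # pad with -inf so boundary maxima are detected
    ext = np.concatenate([[-np.inf], h, [-np.inf]])
    is_peak = (ext[1:-1] > ext[:-2]) & (ext[1:-1] >= ext[2:]) & (ext[1:-1] > half)
    # collapse plateaus: count runs of consecutive peak flags as one
    idx = np.flatnonzero(is_peak)
    if idx.size == 0:
        return 0
    return int(1 + np.sum(np.diff(idx) > 1))


@dataclass
class ClassifiedSynergy:
    """One extracted synergy with its functional label and metrics.

    CoA and FWHM are defined (non-None) only for fundamental synergies.
    """

    label: str
    module: np.ndarray  # (m,)
    primitive: np.ndarray  # (cycle_points,) mean cycle
    trial_index: int
    synergy_index: int
    cluster_id: int
    coa: float | None = None
    fwhm: int | None = None

    @property
    def is_fundamental(self) -> bool:
        return self.label != COMBINED


def classify(decompositions: Sequence[SynergyDecomposition],
             similarity_threshold: float = 0.80,
             linkage_method: str = "average",
             min_cluster_size: int = 2,
             cycle_points: int = CYCLE_POINTS) -> list[ClassifiedSynergy]:
    """Cluster mean-cycle primitives across trials and label them.

    Primitives are unit-normalized and clustered agglomeratively (cosine
    distance, configurable linkage) at distance 1 - similarity_threshold.
    Clusters of at least ``min_cluster_size`` whose medoid shows a single
    activation peak are fundamental and are labelled, in ascending order of
    their mean CoA, swing / touchdown / weight_acceptance / stabilization
    (or the available subset). All remaining primitives are combined.
    """
    if not decompositions:
        raise ValueError("at least one decomposition is required")
    prims, meta = [], []
    for ti, dec in enumerate(decompositions):
        mp = dec.mean_primitives(cycle_points)
        for si in range(mp.shape[0]):
            prims.append(mp[si])
            meta.append((ti, si, dec.w[:, si]))
    x = np.vstack(prims)
    norms = np.linalg.norm(x, axis=1)
    norms[norms <= 0] = 1.0
    xu = x / norms[:, None]
    if len(prims) < 2:
        raise ValueError("classification needs at least two primitives "
                         "(>= 2 trials' decompositions)")
    d = pdist(xu, metric="cosine")
    labels_arr = fcluster(linkage(d, method=linkage_method),
                          t=1.0 - similarity_threshold, criterion="distance")

    sims = 1.0 - squareform(d)
    fundamental_clusters = []
    for cid in np.unique(labels_arr):
        members = np.flatnonzero(labels_arr == cid)
        if members.size < min_cluster_size:
            continue
        sub = sims[np.ix_(members, members)]
        medoid = members[int(np.argmax(sub.sum(axis=1)))]
        if count_peaks(x[medoid]) != 1:
            continue
        coas = [compute_coa(x[mi]) for mi in members]
        fundamental_clusters.append((cid, float(np.mean(coas))))
    fundamental_clusters.sort(key=lambda t: t[1])
    cluster_label = {}
    for k, (cid, _) in enumerate(fundamental_clusters):
        cluster_label[cid] = (FUNDAMENTAL_LABELS[k]
                              if k < len(FUNDAMENTAL_LABELS)
                              else f"fundamental_{k + 1}")

    out = []
    for i, ((ti, si, module), prim) in enumerate(zip(meta, x)):
        cid = int(labels_arr[i])
        label = cluster_label.get(cid, COMBINED)
        cs = ClassifiedSynergy(label=label, module=np.asarray(module),
                               primitive=prim, trial_index=ti,
                               synergy_index=si, cluster_id=cid)
        if label != COMBINED:
            cs.coa = compute_coa(prim)
            cs.fwhm = compute_fwhm(prim)
        out.append(cs)
    return out


def overlaps(primitive_sets: Sequence[Sequence[np.ndarray]]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point primitive overlap counts and their mean curve.

    Each inner sequence holds the fundamental mean-cycle primitives of one
    trial. A primitive covers a time point when it strictly exceeds half of
    its minimum-subtracted maximum (the FWHM convention); the per-point
    overlap count is (number of covering primitives - 1), floored at zero.
    Returns (per-trial counts, mean curve across trials).
    """
    if not primitive_sets:
        raise ValueError("at least one trial's primitives required")
    counts = []
    for prims in primitive_sets:
        prims = [np.asarray(p, dtype=float) for p in prims]
        if len(prims) < 2:
            raise ValueError("overlap analysis needs >= 2 fundamental primitives")
        n = prims[0].size
        above = np.zeros(n, dtype=int)
        for p in prims:
            q = p - p.min()
            above += (q > q.max() / 2).astype(int)
        counts.append(np.maximum(above - 1, 0))
    counts = np.vstack(counts)
    return counts, counts.mean(axis=0)
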