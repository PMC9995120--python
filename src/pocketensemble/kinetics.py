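"""Markov state model of the pocket: features -> tICA -> clustering -> MSM.

The pipeline mirrors standard practice for pocket-dihedral MSMs:

1. sin/cos-encoded backbone (phi, psi) and side-chain (chi1-chi4) dihedrals
   of the binding-site residues,
2. tICA at a fixed lag with *commute mapping* (components scaled by
   sqrt(t_i/2), t_i the implied timescale), retaining the leading components
   that account for a set fraction (default 90%) of kinetic variance,
3. k-means microstates, with k selected by trajectory-split cross-validation
   scored by the rank-10 VAMP-2 score of the test transition matrix,
4. a reversible maximum-likelihood transition matrix on the largest strongly
   connected state set (or the legacy pseudocount/row-normalization
   estimator), and
5. per-frame equilibrium weights pi_s / N_s used to reweight any per-frame
   observable to equilibrium.

``TICA`` and ``MarkovStateModel`` are scikit-learn style estimators;
``fit_tica`` / ``fit_msm`` are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from pocketensemble.structure_io import ResidueID, Trajectory

__all__ = [
    "FeatureMatrix",
    "DiscreteTrajectories",
    "FrameWeights",
    "ClusterModel",
    "ValidationReport",
    "TICA",
    "MarkovStateModel",
    "dihedral_features",
    "featurize_trajectories",
    "fit_tica",
    "cluster_assign",
    "validate_msm",
    "fit_msm",
    "frame_weights",
    "count_matrix",
    "vamp2_score",
    "implied_timescales",
]


# ----------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-trajectory (frames x features) arrays of sin/cos dihedral pairs."""

    trajectories: list[np.ndarray]
    labels: list[str]
    frame_interval_ps: float = 1.0

    def __post_init__(self) -> None:
        self.trajectories = [np.asarray(x, float) for x in self.trajectories]
        n_feat = len(self.labels)
        for x in self.trajectories:
            if x.ndim != 2 or x.shape[1] != n_feat:
                raise ValueError("feature arrays must be (frames, n_features)")
            if not np.isfinite(x).all():
                raise ValueError("features contain non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return sum(x.shape[0] for x in self.trajectories)


@dataclass
class DiscreteTrajectories:
    """Integer state sequences, one array per source trajectory."""

    dtrajs: list[np.ndarray]
    n_states: int
    frame_interval_ps: float = 1.0

    def __post_init__(self) -> None:
        self.dtrajs = [np.asarray(d, dtype=int) for d in self.dtrajs]
        for d in self.dtrajs:
            if d.ndim != 1:
                raise ValueError("discrete trajectories must be 1-D")
            if d.size and (d.min() < 0 or d.max() >= self.n_states):
                raise ValueError("state index out of range")

    @property
    def n_frames(self) -> int:
        return sum(d.size for d in self.dtrajs)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.dtrajs) if self.dtrajs else np.empty(0, int)


@dataclass
class FrameWeights:
    """Per-frame equilibrium weights pi_s / N_s (0 outside the active set)."""

    weights: list[np.ndarray]
    states: list[np.ndarray]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.weights)

    @property
    def total(self) -> float:
        return float(sum(w.sum() for w in self.weights))


@dataclass
class ClusterModel:
    """k-means centroids in commute-mapped tIC space."""

    centroids: np.ndarray

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def assign(self, coords: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment; ties resolve to the lowest index."""
        coords = np.atleast_2d(np.asarray(coords, float))
        d2 = ((coords[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


@dataclass
class ValidationReport:
    """Cross-validated VAMP-2 scores per k and implied timescales vs lag."""

    k_grid: list[int]
    scores_mean: dict[int, float]
    scores_sd: dict[int, float]
    scores_all: dict[int, list[float]]
    chosen_k: int
    its_lags: np.ndarray | None = None  # frames
    its_timescales: np.ndarray | None = None  # (n_lags, n_its) frames


# ----------------------------------------------------------------------
# Featurization
# ----------------------------------------------------------------------

_DIHEDRAL_FUNCS = ("phi", "psi", "chi1", "chi2", "chi3", "chi4")


def dihedral_features(
    traj: Trajectory, site_residues: list[ResidueID]
) -> FeatureMatrix:
    """Sin/cos-encoded phi, psi and chi1-chi4 dihedrals of the site residues.

    Each defined dihedral of each requested residue contributes a (sin, cos)
    column pair, so periodicity introduces no discontinuity.  Glycines
    contribute backbone angles only; a site residue for which no dihedral can
    be resolved raises.
    """
    import mdtraj as md

    mdt = traj.to_mdtraj()
    site = {(str(c), int(r)) for c, r in site_residues}
    top = traj.topology

    cols: list[np.ndarray] = []
    labels: list[str] = []
    seen_residues: set[ResidueID] = set()
    for angle in _DIHEDRAL_FUNCS:
        indices, values = getattr(md, f"compute_{angle}")(mdt)
        for j, quad in enumerate(indices):
            # owner = residue contributing the majority of the 4 atoms
            rids = [(str(top.chain_id[a]), int(top.res_id[a])) for a in quad]
            owner = max(set(rids), key=rids.count)
            if owner not in site:
                continue
            seen_residues.add(owner)
            a = values[:, j]
            cols.append(np.sin(a))
            cols.append(np.cos(a))
            labels.append(f"{owner[0]}:{owner[1]}:{angle}:sin")
            labels.append(f"{owner[0]}:{owner[1]}:{angle}:cos")
    missing = site - seen_residues
    if missing:
        raise ValueError(f"no resolvable dihedrals for site residues: {sorted(missing)}")
    feats = np.column_stack(cols) if cols else np.empty((traj.n_frames, 0))
    return FeatureMatrix([feats], labels, traj.frame_interval_ps)


def featurize_trajectories(
    trajs: list[Trajectory], site_residues: list[ResidueID]
) -> FeatureMatrix:
    """Apply :func:`dihedral_features` to several trajectories, one topology."""
    mats = [dihedral_features(t, site_residues) for t in trajs]
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("trajectories produce inconsistent feature sets")
    return FeatureMatrix(
        [m.trajectories[0] for m in mats], labels, mats[0].frame_interval_ps
    )


# ----------------------------------------------------------------------
# tICA with commute mapping
# ----------------------------------------------------------------------

class TICA(BaseEstimator, TransformerMixin):
    """Time-lagged independent component analysis with commute mapping.

    Solves the generalized eigenproblem ``C_tau v = lambda C_0 v`` on
    symmetrized instantaneous / time-lagged covariances, orders components by
    eigenvalue, converts each to an implied timescale
    ``t_i = -lag / ln|lambda_i|`` and scales the projection by
    ``sqrt(t_i / 2)`` so Euclidean distances approximate kinetic (commute)
    distances.  The retained dimension is the smallest n whose cumulative
    kinetic variance (share of component i proportional to t_i) reaches
    ``var_cutoff``.

    Parameters
    ----------
    lag : int
        Lag time in frames.
    var_cutoff : float
        Fraction of kinetic variance to retain, in (0, 1].
    regularization : float
        Ridge added to the instantaneous covariance diagonal; absorbs rank
        deficiency (e.g. duplicated feature columns).
    """

    def __init__(self, lag: int = 10, var_cutoff: float = 0.9,
                 regularization: float = 1e-8):
        self.lag = lag
        self.var_cutoff = var_cutoff
        self.regularization = regularization

    def fit(self, X, y=None):
        xs = self._as_list(X)
        lag = int(self.lag)
        if lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0 < self.var_cutoff <= 1:
            raise ValueError("var_cutoff must be in (0, 1]")
        usable = [x for x in xs if x.shape[0] > lag]
        if not usable:
            raise ValueError("lag must be shorter than at least one trajectory")
        dim = usable[0].shape[1]
        s0 = np.zeros(dim)
        n_pairs = 0
        for x in usable:
            s0 += x[:-lag].sum(axis=0) + x[lag:].sum(axis=0)
            n_pairs += x.shape[0] - lag
        mean = s0 / (2 * n_pairs)
        c0 = np.zeros((dim, dim))
        ct = np.zeros((dim, dim))
        for x in usable:
            a = x[:-lag] - mean
            b = x[lag:] - mean
            c0 += a.T @ a + b.T @ b
            ct += a.T @ b + b.T @ a
        c0 /= 2 * n_pairs
        ct /= 2 * n_pairs
        c0 += self.regularization * np.eye(dim)
        evals, evecs = scipy.linalg.eigh(ct, c0)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        if np.any(np.abs(evals) > 1 + 1e-6):
            warnings.warn("tICA eigenvalues exceed 1; covariances ill-conditioned")
        lam = np.clip(np.abs(evals), 1e-16, 1 - 1e-12)
        timescales = -lag / np.log(lam)
        share = timescales / timescales.sum()
        cum = np.cumsum(share)
        n = int(np.searchsorted(cum, self.var_cutoff - 1e-12) + 1)
        n = min(n, dim)
        self.mean_ = mean
        self.eigenvalues_ = evals
        self.eigenvectors_ = evecs
        self.timescales_ = timescales
        self.commute_scales_ = np.sqrt(timescales / 2.0)
        self.n_components_ = n
        self.kinetic_variance_ratio_ = float(cum[n - 1])
        return self

    def transform(self, X):
        xs = self._as_list(X)
        n = self.n_components_
        out = [
            (x - self.mean_) @ self.eigenvectors_[:, :n] * self.commute_scales_[:n]
            for x in xs
        ]
        return out if isinstance(X, (list, FeatureMatrix)) else out[0]

    @staticmethod
    def _as_list(X) -> list[np.ndarray]:
        if isinstance(X, FeatureMatrix):
            return X.trajectories
        if isinstance(X, list):
            return [np.asarray(x, float) for x in X]
        return [np.asarray(X, float)]


def fit_tica(features: FeatureMatrix, lag: int, var_cutoff: float = 0.9,
             regularization: float = 1e-8) -> TICA:
    """Fit :class:`TICA` on a feature matrix (lag in frames)."""
    return TICA(lag=lag, var_cutoff=var_cutoff,
                regularization=regularization).fit(features)


# ----------------------------------------------------------------------
# Clustering
# ----------------------------------------------------------------------

def cluster_assign(
    tica_coords: list[np.ndarray],
    k: int,
    seed: int,
    fit_subset: list[int] | None = None,
    frame_interval_ps: float = 1.0,
    n_init: int = 10,
) -> tuple[ClusterModel, DiscreteTrajectories]:
    """k-means in tIC space; every frame assigned to its nearest centroid.

    ``fit_subset`` (trajectory indices) restricts the k-means *fit* to a
    training set; all trajectories, fit or held out, are then assigned by
    Euclidean proximity to the centroids (ties to the lowest centroid index).
    """
    coords = [np.atleast_2d(np.asarray(x, float)) for x in tica_coords]
    fit_idx = list(range(len(coords))) if fit_subset is None else list(fit_subset)
    fit_data = np.vstack([coords[i] for i in fit_idx])
    if k > fit_data.shape[0]:
        raise ValueError(f"k={k} exceeds number of fit frames ({fit_data.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(fit_data)
    model = ClusterModel(np.asarray(km.cluster_centers_, float))
    dtrajs = [model.assign(x) for x in coords]
    return model, DiscreteTrajectories(dtrajs, k, frame_interval_ps)


# ----------------------------------------------------------------------
# Transition counting, VAMP-2, MSM estimation
# ----------------------------------------------------------------------

def count_matrix(dtrajs: DiscreteTrajectories, lag: int,
                 sliding: bool = True) -> np.ndarray:
    """Transition count matrix at ``lag`` frames (sliding window by default)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    k = dtrajs.n_states
    c = np.zeros((k, k))
    step = 1 if sliding else lag
    for d in dtrajs.dtrajs:
        if d.size <= lag:
            continue
        i = d[:-lag:step]
        j = d[lag:][::step] if not sliding else d[lag:]
        np.add.at(c, (i, j), 1.0)
    return c


def vamp2_score(dtrajs: DiscreteTrajectories, lag: int, rank: int = 10) -> float:
    """Rank-r VAMP-2 score of the transition statistics at ``lag``.

    Sum of the ``rank`` largest squared singular values of
    ``C00^(-1/2) C01 C11^(-1/2)`` built from the transition pair counts.
    """
    c01 = count_matrix(dtrajs, lag)
    total = c01.sum()
    if total == 0:
        raise ValueError("no transition pairs at this lag")
    c01 = c01 / total
    p0 = c01.sum(axis=1)
    p1 = c01.sum(axis=0)
    keep = (p0 > 0) & (p1 > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 states visited in the transition pairs")
    c01 = c01[np.ix_(keep, keep)]
    w0 = 1.0 / np.sqrt(c01.sum(axis=1))
    w1 = 1.0 / np.sqrt(c01.sum(axis=0))
    kmat = (w0[:, None] * c01) * w1[None, :]
    s = np.linalg.svd(kmat, compute_uv=False)
    return float(np.sum(s[:rank] ** 2))


def _largest_connected_set(c: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the count graph (most counts)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(c > 0), directed=True,
                                          connection="strong")
    best, best_counts, best_size = 0, -1.0, -1
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        counts = c[np.ix_(members, members)].sum()
        if (len(members), counts) > (best_size, best_counts):
            best, best_counts, best_size = comp, counts, len(members)
    return np.flatnonzero(labels == best)


def _reversible_mle(c: np.ndarray, tol: float, max_iter: int
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Fixed-point reversible MLE of a transition matrix from counts.

    Iterates ``x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`` on the symmetric
    flux matrix x until the stationary distribution moves less than ``tol``.
    """
    csym = c + c.T
    ci = c.sum(axis=1)
    x = csym.copy()
    if x.sum() == 0:
        raise ValueError("no observed transitions")
    x /= x.sum()
    pi = x.sum(axis=1)
    support = csym > 0
    for it in range(1, max_iter + 1):
        xi = x.sum(axis=1)
        q = ci / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(support, csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        pi_new = x_new.sum(axis=1)
        delta = np.max(np.abs(pi_new - pi))
        x, pi = x_new, pi_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(residual {delta:.3g})"
        )
    t = x / x.sum(axis=1, keepdims=True)
    return t, pi, it


class MarkovStateModel(BaseEstimator):
    """Reversible (or legacy pseudocount) Markov state model estimator.

    Parameters
    ----------
    lag : int
        Lag time in frames; counts use a sliding window.
    estimator : {"reversible_mle", "pseudocount_rownorm"}
        ``reversible_mle`` maximizes the likelihood under detailed balance on
        the largest strongly connected state set.  ``pseudocount_rownorm``
        adds 1/k to every count and row-normalizes (legacy-dataset variant);
        its stationary distribution comes from the leading left eigenvector.
    tol, max_iter :
        Convergence control of the reversible fixed-point iteration
        (max |change in pi| per sweep).

    Fitted attributes: ``count_matrix_`` (full k x k), ``active_set_``,
    ``transition_matrix_`` / ``stationary_distribution_`` (on the active
    set), ``index_map_`` (full state -> active index, -1 outside).
    """

    def __init__(self, lag: int = 1, estimator: str = "reversible_mle",
                 tol: float = 1e-10, max_iter: int = 1_000_000):
        self.lag = lag
        self.estimator = estimator
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, dtrajs: DiscreteTrajectories, y=None):
        if self.estimator not in ("reversible_mle", "pseudocount_rownorm"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        c_full = count_matrix(dtrajs, int(self.lag))
        if c_full.sum() == 0:
            raise ValueError("no transition pairs observed at this lag")
        active = _largest_connected_set(c_full)
        c = c_full[np.ix_(active, active)]
        if self.estimator == "reversible_mle":
            if len(active) == 1:
                t, pi, it = np.ones((1, 1)), np.ones(1), 0
            else:
                t, pi, it = _reversible_mle(c, self.tol, self.max_iter)
        else:
            k = c.shape[0]
            cpn = c + 1.0 / k
            t = cpn / cpn.sum(axis=1, keepdims=True)
            evals, evecs = scipy.linalg.eig(t, left=True, right=False)
            lead = np.argmin(np.abs(evals - 1.0))
            pi = np.real(evecs[:, lead])
            pi = np.abs(pi) / np.abs(pi).sum()
            it = 0
        index_map = -np.ones(dtrajs.n_states, dtype=int)
        index_map[active] = np.arange(len(active))
        self.count_matrix_ = c_full
        self.active_set_ = active
        self.index_map_ = index_map
        self.transition_matrix_ = t
        self.stationary_distribution_ = pi
        self.n_iter_ = it
        self.n_states_full_ = dtrajs.n_states
        return self

    # -- derived quantities -------------------------------------------
    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales -lag/ln|lambda_i| (frames), slowest first."""
        evals = np.linalg.eigvals(self.transition_matrix_)
        evals = np.sort(np.abs(evals))[::-1][1:]  # drop the stationary eigenvalue
        evals = np.clip(evals, 1e-16, 1 - 1e-15)
        its = -self.lag / np.log(evals)
        return its[:n] if n is not None else its

    def pi_full(self) -> np.ndarray:
        """Stationary distribution embedded in the full state space (0 outside)."""
        pi = np.zeros(self.n_states_full_)
        pi[self.active_set_] = self.stationary_distribution_
        return pi


def fit_msm(dtrajs: DiscreteTrajectories, lag: int,
            estimator: str = "reversible_mle", tol: float = 1e-10,
            max_iter: int = 1_000_000) -> MarkovStateModel:
    """Fit a :class:`MarkovStateModel` at ``lag`` frames."""
    return MarkovStateModel(lag=lag, estimator=estimator, tol=tol,
                            max_iter=max_iter).fit(dtrajs)


def frame_weights(msm: MarkovStateModel, dtrajs: DiscreteTrajectories
                  ) -> FrameWeights:
    """Equilibrium weight of every frame: pi_s / N_s for its state s.

    N_s is the number of frames assigned to state s over all trajectories;
    frames outside the MSM's active set get weight 0.  Weights over active
    frames sum to 1.
    """
    pi_full = msm.pi_full()
    counts = np.bincount(dtrajs.concatenated(), minlength=dtrajs.n_states)
    active_mask = msm.index_map_ >= 0
    assert not np.any(active_mask & (counts == 0)), "active state with no frames"
    per_state = np.zeros(dtrajs.n_states)
    nz = counts > 0
    per_state[nz] = pi_full[nz] / counts[nz]
    weights = [per_state[d] for d in dtrajs.dtrajs]
    return FrameWeights(weights=weights, states=[d.copy() for d in dtrajs.dtrajs])


# ----------------------------------------------------------------------
# Cross-validated model selection
# ----------------------------------------------------------------------

def validate_msm(
    tica_coords: list[np.ndarray],
    k_grid: list[int],
    msm_lag: int,
    n_splits: int = 5,
    seed: int = 0,
    rank: int = 10,
    its_lags: list[int] | None = None,
    frame_interval_ps: float = 1.0,
) -> ValidationReport:
    """Choose the microstate count k by trajectory-split cross-validation.

    For each k and each of ``n_splits`` random 50/50 trajectory splits:
    cluster the training trajectories, assign the held-out ones to the
    nearest centroids, and score the *test* transition statistics at
    ``msm_lag`` with the rank-10 VAMP-2 score.  The chosen k maximizes the
    mean score; implied timescales over ``its_lags`` are reported for it.
    """
    n_traj = len(tica_coords)
    if n_traj < 2:
        raise ValueError("need at least 2 trajectories for cross-validation")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_splits)
    scores_all: dict[int, list[float]] = {k: [] for k in k_grid}
    for rep, sseed in enumerate(split_seeds):
        srng = np.random.default_rng(sseed)
        perm = srng.permutation(n_traj)
        n_train = max(1, n_traj // 2)
        train = sorted(perm[:n_train].tolist())
        test = sorted(perm[n_train:].tolist())
        for k in k_grid:
            _, dtrajs = cluster_assign(
                tica_coords, k, seed=int(sseed), fit_subset=train,
                frame_interval_ps=frame_interval_ps,
            )
            test_d = DiscreteTrajectories(
                [dtrajs.dtrajs[i] for i in test], k, frame_interval_ps
            )
            scores_all[k].append(vamp2_score(test_d, msm_lag, rank=rank))
    scores_mean = {k: float(np.mean(v)) for k, v in scores_all.items()}
    scores_sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                 for k, v in scores_all.items()}
    chosen_k = max(k_grid, key=lambda k: scores_mean[k])
    its_arr = lags_arr = None
    if its_lags:
        _, dtrajs = cluster_assign(tica_coords, chosen_k, seed=seed,
                                   frame_interval_ps=frame_interval_ps)
        rows = []
        for lg in its_lags:
            msm = fit_msm(dtrajs, lg)
            rows.append(msm.timescales(n=min(5, chosen_k - 1)))
        n_its = max(len(r) for r in rows)
        its_arr = np.full((len(its_lags), n_its), np.nan)
        for i, r in enumerate(rows):
            its_arr[i, : len(r)] = r
        lags_arr = np.asarray(its_lags)
    return ValidationReport(
        k_grid=list(k_grid),
        scores_mean=scores_mean,
        scores_sd=scores_sd,
        scores_all=scores_all,
        chosen_k=chosen_k,
        its_lags=lags_arr,
        its_timescales=its_arr,
    )


def implied_timescales(dtrajs: DiscreteTrajectories, lags: list[int],
                       n_its: int = 5,
                       estimator: str = "reversible_mle") -> np.ndarray:
    """Implied timescales (frames) for a grid of lags; rows align with ``lags``."""
    out = np.full((len(lags), n_its), np.nan)
    for i, lg in enumerate(lags):
        msm = fit_msm(dtrajs, lg, estimator=estimator)
        its = msm.timescales(n=n_its)
        out[i, : len(its)] = its
    return out
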