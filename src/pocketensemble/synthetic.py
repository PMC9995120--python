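"""Ground-truth synthetic fixtures for every pipeline stage.

Two families of fixtures stand in for molecular-dynamics data:

* **Cavity cages** — pseudo-atom spherical shells with a known interior
  cavity, an optional aperture ("lid") and an optional interior blocker
  cluster that mimics a gating side chain.  They exercise the grid pocket
  detector against brute-force and analytic volume estimates.

* **Reference ensembles** — hidden Markov chains with a known reversible
  transition matrix emitting (i) dihedral-like periodic features (von Mises
  angles encoded as sin/cos), (ii) state-coupled pocket volumes (truncated
  normals), and (iii) per-frame docking scores (normals).  The stationary
  distribution, p_open at any threshold, and the aggregate binding free
  energy are all available in closed form, so featurize -> tICA -> cluster
  -> MSM -> p_open / dG recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pocketensemble.constants import DEFAULT_TEMPERATURE_K, R_KCAL_PER_MOL_K, vdw_radius
from pocketensemble.kinetics import FeatureMatrix
from pocketensemble.msm_dock import StateSample
from pocketensemble.pocket_stats import PocketVolumeSeries
from pocketensemble.structure_io import LigandCoords, Structure

__all__ = [
    "EnsembleSpec",
    "GroundTruth",
    "make_cavity_structure",
    "simulate_reference_ensemble",
    "make_docking_table",
    "stationary_distribution",
]


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary left eigenvector of a row-stochastic matrix."""
    t = np.asarray(t, float)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    evals, evecs = np.linalg.eig(t.T)
    lead = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, lead])
    pi = np.abs(pi)
    return pi / pi.sum()


def _default_T() -> np.ndarray:
    # reversible 3-state chain with pi = (0.5, 0.3, 0.2) by construction
    return np.array(
        [
            [0.95, 0.03, 0.02],
            [0.05, 0.93, 0.02],
            [0.05, 0.03, 0.92],
        ]
    )


@dataclass
class EnsembleSpec:
    """Generator settings for a reference ensemble with known ground truth.

    Defaults describe a three-state pocket (closed / partly open / open)
    with well-separated dihedral emissions (kappa = 8), volume emissions of
    40 / 80 / 150 A^3, docking-score emissions of -3 / -5.5 / -8 kcal/mol,
    and 20 trajectories saved every 20 ps.
    """

    n_states: int = 3
    T_true: np.ndarray = field(default_factory=_default_T)
    angle_means: np.ndarray | None = None  # (n_states, n_angles) radians
    kappa: float = 8.0
    n_angles: int = 4
    volume_means: np.ndarray = field(
        default_factory=lambda: np.array([40.0, 80.0, 150.0])
    )
    volume_sds: np.ndarray = field(
        default_factory=lambda: np.array([12.0, 15.0, 20.0])
    )
    score_means: np.ndarray = field(
        default_factory=lambda: np.array([-3.0, -5.5, -8.0])
    )
    score_sds: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5, 0.5]))
    n_trajectories: int = 20
    frames_per_trajectory: int = 10_000
    frame_interval_ps: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.T_true = np.asarray(self.T_true, float)
        k = self.n_states
        if self.T_true.shape != (k, k):
            raise ValueError("T_true must be n_states x n_states")
        if np.any(self.T_true < 0) or not np.allclose(self.T_true.sum(axis=1), 1.0):
            raise ValueError("T_true must be row-stochastic")
        if self.kappa <= 0:
            raise ValueError("concentrations must be positive")
        if np.any(np.asarray(self.volume_sds) < 0) or np.any(np.asarray(self.score_sds) < 0):
            raise ValueError("emission sds must be non-negative")
        if self.angle_means is None:
            # evenly spread circular means, shifted per angle for variety
            s = np.arange(k)[:, None]
            j = np.arange(self.n_angles)[None, :]
            self.angle_means = (2 * np.pi * s / k + 0.5 * j) % (2 * np.pi)
        self.angle_means = np.asarray(self.angle_means, float)
        if self.angle_means.shape != (k, self.n_angles):
            raise ValueError("angle_means must be (n_states, n_angles)")

    # -- closed-form ground truths ------------------------------------
    def pi_true(self) -> np.ndarray:
        return stationary_distribution(self.T_true)

    def p_open_true(self, threshold: float) -> float:
        """Sum_s pi_s P(v >= threshold | s) under the 0-truncated normal emissions."""
        pi = self.pi_true()
        p = 0.0
        for s in range(self.n_states):
            mu, sd = self.volume_means[s], self.volume_sds[s]
            if sd == 0:
                tail = float(mu >= threshold)
            else:
                a = (0.0 - mu) / sd
                tail = float(stats.truncnorm.sf(threshold, a, np.inf, loc=mu, scale=sd))
            p += pi[s] * tail
        return float(p)

    def dG_true(self, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
        """-RT ln( sum_s pi_s exp(-mu_s/RT + sigma_s^2/(2 RT^2)) ) (kcal/mol)."""
        rt = R_KCAL_PER_MOL_K * temperature
        pi = self.pi_true()
        terms = pi * np.exp(-self.score_means / rt + self.score_sds**2 / (2 * rt**2))
        return float(-rt * np.log(terms.sum()))


@dataclass
class GroundTruth:
    """Closed-form reference values implied by an :class:`EnsembleSpec`."""

    pi_true: np.ndarray
    p_open_true: float
    threshold: float
    dG_true: float
    temperature: float


def make_cavity_structure(
    shell_radius: float = 10.0,
    atom_spacing: float = 1.8,
    lid_fraction: float = 0.0,
    blocker: bool = False,
    seed: int = 0,
) -> tuple[Structure, LigandCoords, float]:
    """Pseudo-atom spherical cage with a central cavity of known size.

    Carbon pseudo-atoms tile a sphere of radius ``shell_radius`` (Fibonacci
    lattice, ~``atom_spacing`` between neighbours, slightly jittered by
    ``seed``).  ``lid_fraction`` removes a polar cap of that fractional
    surface area, opening the cage; ``blocker`` adds a small interior atom
    cluster emulating a gating side chain.  A pseudo-ligand of dummy carbon
    atoms fills the cavity so that the ligand-proximity filter spans it.

    Returns (structure, pseudo-ligand, analytic interior-volume estimate in
    A^3: the sphere of radius ``shell_radius - (r_C + 1.4)`` minus the
    blocker exclusion, ignoring the aperture).
    """
    if shell_radius < 4.0:
        raise ValueError("shell_radius must be at least 4 A")
    r_excl = vdw_radius("C") + 1.4  # atom vdW + default probe
    if atom_spacing > 2.0 * r_excl / np.sqrt(2):
        raise ValueError(
            f"atom_spacing {atom_spacing} too coarse to close the shell "
            f"(needs <= {2.0 * r_excl / np.sqrt(2):.2f} A)"
        )
    rng = np.random.default_rng(seed)
    n = max(16, int(np.ceil(4 * np.pi * shell_radius**2 / atom_spacing**2)))
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.clip(1 - z**2, 0, 1))
    theta = golden * i
    pts = shell_radius * np.column_stack(
        [r_xy * np.cos(theta), r_xy * np.sin(theta), z]
    )
    pts += rng.normal(scale=0.02 * atom_spacing, size=pts.shape)
    if lid_fraction > 0:
        # lid_fraction 0 -> closed shell, 1 -> full upper hemisphere removed
        keep = pts[:, 2] / shell_radius <= 1.0 - lid_fraction
        pts = pts[keep]
    if blocker:
        # small side-chain-like cluster reaching into the cavity from the wall
        base = np.array([0.6 * shell_radius, 0.0, 0.0])
        offsets = np.array(
            [[0, 0, 0], [-1.5, 0, 0], [-3.0, 0, 0], [-1.5, 1.2, 0], [-1.5, -1.2, 0]]
        )
        pts = np.vstack([pts, base + offsets])
    n_atoms = pts.shape[0]
    structure = Structure(
        atom_name=np.array(["C"] * n_atoms),
        element=np.array(["C"] * n_atoms),
        res_id=np.arange(1, n_atoms + 1),
        res_name=np.array(["SHL"] * n_atoms),
        chain_id=np.array(["A"] * n_atoms),
        coords=pts,
    )
    # dummy-ligand lattice filling the cavity (2 A spacing)
    r_inner = shell_radius - r_excl
    grid = np.arange(-r_inner, r_inner + 1e-9, 2.0)
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    lig_pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lig_pts = lig_pts[np.linalg.norm(lig_pts, axis=1) <= max(r_inner - 0.5, 0.5)]
    if lig_pts.shape[0] == 0:
        lig_pts = np.zeros((1, 3))
    ligand = LigandCoords(lig_pts, np.array(["C"] * lig_pts.shape[0]))
    analytic = 4.0 / 3.0 * np.pi * max(r_inner, 0.0) ** 3
    if blocker:
        # blocker atoms exclude roughly one merged sphere reaching the centre
        analytic -= 4.0 / 3.0 * np.pi * r_excl**3 * 2.0
        analytic = max(analytic, 0.0)
    return structure, ligand, float(analytic)


def simulate_reference_ensemble(
    spec: EnsembleSpec, threshold: float = 120.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> tuple[FeatureMatrix, PocketVolumeSeries, list[np.ndarray], GroundTruth]:
    """Sample hidden chains and their feature / volume emissions.

    Returns the sin/cos feature matrix, the per-frame pocket-volume series,
    the hidden state sequences, and the closed-form ground truth (stationary
    distribution, p_open at ``threshold``, aggregate dG).
    """
    rng = np.random.default_rng(spec.seed)
    pi = spec.pi_true()
    k = spec.n_states
    cdf = np.cumsum(spec.T_true, axis=1)
    hidden: list[np.ndarray] = []
    feats: list[np.ndarray] = []
    vols: list[np.ndarray] = []
    for _ in range(spec.n_trajectories):
        n = spec.frames_per_trajectory
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(k, p=pi)
        u = rng.random(n)
        for t in range(1, n):
            states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
        hidden.append(states)
        # von Mises angles per state, sin/cos encoded
        angles = rng.vonmises(spec.angle_means[states], spec.kappa)
        f = np.empty((n, 2 * spec.n_angles))
        f[:, 0::2] = np.sin(angles)
        f[:, 1::2] = np.cos(angles)
        feats.append(f)
        # truncated-normal volumes
        v = np.empty(n)
        for s in range(k):
            mask = states == s
            mu, sd = spec.volume_means[s], spec.volume_sds[s]
            if sd == 0:
                v[mask] = mu
            else:
                a = (0.0 - mu) / sd
                v[mask] = stats.truncnorm.rvs(
                    a, np.inf, loc=mu, scale=sd, size=mask.sum(), random_state=rng
                )
        vols.append(v)
    labels = [
        f"state-angle:{j}:{fn}" for j in range(spec.n_angles) for fn in ("sin", "cos")
    ]
    fm = FeatureMatrix(feats, labels, spec.frame_interval_ps)
    series = PocketVolumeSeries.from_frame_volumes(
        vols, frame_interval_ps=spec.frame_interval_ps
    )
    truth = GroundTruth(
        pi_true=pi,
        p_open_true=spec.p_open_true(threshold),
        threshold=threshold,
        dG_true=spec.dG_true(temperature),
        temperature=temperature,
    )
    return fm, series, hidden, truth


def make_docking_table(
    spec: EnsembleSpec,
    hidden: list[np.ndarray],
    samples: list[StateSample],
    path=None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Docking-score table for sampled frames, drawn from hidden-state emissions.

    Each sampled frame (traj, frame) receives a score from the normal
    emission of its *hidden* state (not the MSM microstate used for
    sampling).  Returns the table (written to ``path`` if given) and the
    closed-form aggregate ``dG_true``.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    rows = []
    for sample in samples:
        for (t, f) in sample.frames:
            s_hidden = int(hidden[t][f])
            mu, sd = spec.score_means[s_hidden], spec.score_sds[s_hidden]
            g = float(mu if sd == 0 else rng.normal(mu, sd))
            rows.append({"traj_id": t, "frame": f, "score_kcal_mol": g})
    df = pd.DataFrame(rows, columns=["traj_id", "frame", "score_kcal_mol"])
    if path is not None:
        df.to_csv(path, index=False)
    return df, spec.dG_true()
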