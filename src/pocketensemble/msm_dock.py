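"""Ensemble docking over an MSM: structure sampling, box definition, aggregation.

Per-conformation docking scores g (kcal/mol, negative favorable) are consumed
from tables and combined into one ensemble binding free energy.  Each docked
structure f, assigned to MSM state s(f), contributes its micro association
constant K_eq,f = exp(-g_f / RT), weighted by pi_s / N_s (state equilibrium
probability over the number of docked structures in that state):

    dG_total = -RT ln( sum_f (pi_s(f) / N_s(f)) * K_eq,f )

With one structure per state this reduces exactly to
``-RT ln(sum_s pi_s K_eq,s)``.  The result converts to a standard-state
dissociation constant via K_d = exp(dG_total / RT) * 1 M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pocketensemble.constants import DEFAULT_TEMPERATURE_K, R_KCAL_PER_MOL_K
from pocketensemble.kinetics import DiscreteTrajectories, MarkovStateModel
from pocketensemble.structure_io import AtomSelection, Trajectory

__all__ = [
    "StateSample",
    "DockingRecord",
    "AffinityEstimate",
    "DockingBox",
    "sample_docking_structures",
    "define_docking_box",
    "ingest_docking_scores",
    "aggregate_binding_free_energy",
    "deltaG_to_Kd",
    "Kd_to_deltaG",
]

FrameID = tuple[int, int]  # (trajectory index, frame index)


@dataclass
class StateSample:
    """Frames drawn from one MSM state for docking."""

    state: int
    requested: int
    frames: list[FrameID]
    seed: int

    @property
    def n(self) -> int:
        return len(self.frames)


@dataclass
class DockingRecord:
    """Best docking score for one sampled conformation, keyed to its state."""

    traj: int
    frame: int
    state: int
    score: float  # kcal/mol
    pose_rmsd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("docking score must be finite")


@dataclass
class AffinityEstimate:
    """Aggregate binding free energy and its standard-state dissociation constant."""

    dG_total: float  # kcal/mol
    K_eq: float  # dimensionless association constant
    K_d: float  # molar
    temperature: float
    R: float = R_KCAL_PER_MOL_K
    sem: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class DockingBox:
    """Cubic (or rectangular) docking search box in the aligned frame."""

    center: np.ndarray  # (3,) A
    edges: np.ndarray  # (3,) A

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.edges = np.asarray(self.edges, float)
        if np.any(self.edges <= 0):
            raise ValueError("box edge lengths must be positive")

    def to_text(self) -> str:
        cx, cy, cz = (float(v) for v in self.center)
        ex, ey, ez = (float(v) for v in self.edges)
        return (
            f"center_x = {cx!r}\ncenter_y = {cy!r}\ncenter_z = {cz!r}\n"
            f"size_x = {ex!r}\nsize_y = {ey!r}\nsize_z = {ez!r}\n"
        )


def sample_docking_structures(
    msm: MarkovStateModel,
    dtrajs: DiscreteTrajectories,
    base: int = 3,
    scale: int = 2000,
    seed: int = 0,
) -> list[StateSample]:
    """Draw frames per active state: N_s = max(base, round(pi_s * scale)).

    Sampling is uniform without replacement within a state, capped (with a
    warning) at the number of frames assigned to that state.
    """
    if base < 1:
        raise ValueError("base must be >= 1")
    rng = np.random.default_rng(seed)
    frames_by_state: dict[int, list[FrameID]] = {}
    for t, d in enumerate(dtrajs.dtrajs):
        for f, s in enumerate(d):
            frames_by_state.setdefault(int(s), []).append((t, f))
    pi_full = msm.pi_full()
    samples: list[StateSample] = []
    for s in msm.active_set_:
        s = int(s)
        pool = frames_by_state.get(s, [])
        n_req = max(base, int(round(pi_full[s] * scale)))
        n_draw = min(n_req, len(pool))
        if n_draw < n_req:
            warnings.warn(
                f"state {s}: requested {n_req} structures but only "
                f"{len(pool)} frames assigned; taking all"
            )
        idx = rng.choice(len(pool), size=n_draw, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
        samples.append(StateSample(state=s, requested=n_req, frames=chosen,
                                   seed=seed))
    return samples


def define_docking_box(
    aligned_traj: Trajectory,
    site_selection: AtomSelection,
    edge: float = 22.5,
) -> DockingBox:
    """Center the box on the site-selection centroid of the ensemble mean structure.

    The trajectory must already be aligned (see
    :func:`pocketensemble.superposition.iterative_ensemble_align` on the same
    selection); the returned center is then the origin of that aligned
    coordinate system up to the residual mean displacement.
    """
    site_selection.validate(aligned_traj.topology.n_atoms)
    if len(site_selection) == 0:
        raise ValueError("empty site selection")
    mean = aligned_traj.frames.mean(axis=0)
    center = mean[site_selection.indices].mean(axis=0)
    return DockingBox(center=center, edges=np.full(3, float(edge)))


def ingest_docking_scores(
    path: str | Path,
    dtrajs: DiscreteTrajectories,
    msm: MarkovStateModel | None = None,
) -> list[DockingRecord]:
    """Read a ``traj_id,frame,score_kcal_mol[,pose_rmsd_A]`` CSV into records.

    ``traj_id`` may be an integer index or a ``traj<N>`` label.  Multiple
    poses of a frame collapse to the best (lowest) score; frames assigned to
    states outside the MSM active set are dropped with a warning.
    """
    df = pd.read_csv(path)
    required = {"traj_id", "frame", "score_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"docking CSV must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("no docking records in file")
    if not np.issubdtype(df["score_kcal_mol"].dtype, np.number):
        raise ValueError("non-numeric docking scores")
    active = set(int(s) for s in msm.active_set_) if msm is not None else None
    best: dict[FrameID, DockingRecord] = {}
    dropped = 0
    for _, row in df.iterrows():
        tid = row["traj_id"]
        t = int(str(tid).replace("traj", "")) if isinstance(tid, str) else int(tid)
        f = int(row["frame"])
        if t < 0 or t >= len(dtrajs.dtrajs) or f >= dtrajs.dtrajs[t].size:
            raise KeyError(f"frame ({tid}, {f}) not found in discrete trajectories")
        s = int(dtrajs.dtrajs[t][f])
        if active is not None and s not in active:
            dropped += 1
            continue
        score = float(row["score_kcal_mol"])
        rmsd = float(row["pose_rmsd_A"]) if "pose_rmsd_A" in df.columns else None
        key = (t, f)
        if key not in best or score < best[key].score:
            best[key] = DockingRecord(t, f, s, score, rmsd)
    if dropped:
        warnings.warn(f"dropped {dropped} records outside the MSM active set")
    if not best:
        raise ValueError("no docking records after filtering")
    return list(best.values())


def aggregate_binding_free_energy(
    records: list[DockingRecord],
    msm: MarkovStateModel,
    samples: list[StateSample] | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> AffinityEstimate:
    """Boltzmann-weighted aggregation of per-structure docking scores.

    ``dG_total = -RT ln( sum_f (pi_s(f)/N_s(f)) exp(-g_f/RT) )`` where N_s
    is the number of docked structures in state s (from ``samples`` when
    given, else counted from the records).  Active states with no docked
    structure contribute zero and are logged.  Evaluated with log-sum-exp
    for numerical safety.
    """
    if not records:
        raise ValueError("no docking records")
    rt = R_KCAL_PER_MOL_K * temperature
    pi_full = msm.pi_full()
    if samples is not None:
        n_by_state = {s.state: s.n for s in samples}
        for r in records:
            if n_by_state.get(r.state, 0) <= 0:
                raise ValueError(f"record in state {r.state} has no sample entry")
    else:
        n_by_state = {}
        for r in records:
            n_by_state[r.state] = n_by_state.get(r.state, 0) + 1
    covered = set(n_by_state) & {int(s) for s in msm.active_set_}
    uncovered = [int(s) for s in msm.active_set_
                 if int(s) not in {r.state for r in records}]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} active states have no docked structures and "
            "contribute zero to the aggregate"
        )
    with np.errstate(divide="ignore"):
        log_terms = np.array(
            [np.log(pi_full[r.state] / n_by_state[r.state]) - r.score / rt
             for r in records]
        )
    if not np.isfinite(log_terms).any():
        raise ValueError("total weight of represented states is zero")
    log_keq = logsumexp(log_terms)
    dg = float(-rt * log_keq)
    return AffinityEstimate(
        dG_total=dg,
        K_eq=float(np.exp(log_keq)),
        K_d=deltaG_to_Kd(dg, temperature),
        temperature=temperature,
    )


def deltaG_to_Kd(dG: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Standard-state dissociation constant (molar): K_d = exp(dG / RT) * 1 M."""
    if not np.isfinite(dG):
        raise ValueError("dG must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(dG / (R_KCAL_PER_MOL_K * temperature)))


def Kd_to_deltaG(Kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) from a molar dissociation constant."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(R_KCAL_PER_MOL_K * temperature * np.log(Kd))
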