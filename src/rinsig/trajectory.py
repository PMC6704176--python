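"""Trajectory descriptors: RMSD, RMSF, radius of gyration, H-bond
time series and extended/turn conformation calls.

A trajectory is a fixed topology plus per-frame coordinate sets (Å)
with frame times in ns. Summaries report nm alongside Å to match the
conventions of molecular-dynamics plots (1 nm = 10 Å exactly).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import superpose
from .interactions import Cutoffs, InteractionEdge, detect_hbonds
from .structio import StructureModel


@dataclass
class Trajectory:
    topology: StructureModel
    frames: np.ndarray          # (n_frames, n_atoms, 3) in Å
    times: np.ndarray = None    # ns per frame  # type: ignore[assignment]

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        n_atoms = self.topology.n_atoms
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise ValueError(
                f"frames must be (n_frames, {n_atoms}, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, float)
        if self.times.shape != (self.n_frames,) or \
                np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing, one per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, index: int) -> StructureModel:
        """Topology with the coordinates of one frame."""
        model = self.topology.copy()
        model.set_coords(self.frames[index])
        model.model_id = index + 1
        return model

    def frame_index_at(self, time_ns: float) -> int:
        """Index of the frame closest in time (exact-or-nearest)."""
        return int(np.argmin(np.abs(self.times - time_ns)))


def rmsd_series(traj: Trajectory, reference: int | np.ndarray = 0,
                superpose_frames: bool = True) -> np.ndarray:
    """Per-frame heavy-atom RMSD (Å) vs a reference frame.

    ``reference`` is a frame index (default: the initial conformation)
    or an external (n_atoms, 3) coordinate set. With
    ``superpose_frames=True`` each frame is optimally (Kabsch)
    superposed onto the reference first.
    """
    ref = (traj.frames[reference] if isinstance(reference, (int, np.integer))
           else np.asarray(reference, float))
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        if superpose_frames:
            out[i] = superpose(frame, ref).rmsd
        else:
            out[i] = float(np.sqrt(((frame - ref) ** 2).sum(axis=1).mean()))
    return out


def _superposed_frames(traj: Trajectory, n_passes: int = 1) -> np.ndarray:
    """Frames superposed onto their running mean structure."""
    frames = traj.frames.copy()
    for _ in range(n_passes):
        mean = frames.mean(axis=0)
        frames = np.array([superpose(f, mean).apply(f) for f in frames])
    return frames


def rmsf(traj: Trajectory, superpose_frames: bool = True,
         per_atom: bool = False) -> np.ndarray:
    """Positional fluctuation around the time-mean structure (Å).

    Per residue (default), the root of the atom-averaged mean-square
    deviation from each atom's time-mean position; ``per_atom=True``
    returns the per-atom values instead. With superposition the frames
    are first fitted onto the mean structure (one iteration).
    """
    frames = _superposed_frames(traj) if superpose_frames else traj.frames
    mean = frames.mean(axis=0)
    msf = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    if per_atom:
        return np.sqrt(msf)
    out = []
    i = 0
    for res in traj.topology.residues():
        n = len(res.atoms)
        out.append(np.sqrt(msf[i:i + n].mean()))
        i += n
    return np.array(out)


def rg_series(traj: Trajectory, mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration (Å), mass-weighted by default."""
    if mass_weighted:
        w = np.array([a.mass for a in traj.topology.atoms()])
    else:
        w = np.ones(traj.frames.shape[1])
    w = w / w.sum()
    com = (traj.frames * w[None, :, None]).sum(axis=1, keepdims=True)
    sq = ((traj.frames - com) ** 2).sum(axis=2)
    return np.sqrt((sq * w[None, :]).sum(axis=1))


def hbond_timeseries(traj: Trajectory, times: list[float] | None = None,
                     class_filter: str = "any",
                     cutoffs: Cutoffs | None = None
                     ) -> list[tuple[float, int, list[InteractionEdge]]]:
    """H-bond count and identity at the selected times.

    ``times`` selects frames by nearest time in ns (all frames when
    omitted); ``class_filter`` restricts to ``'MM'``, ``'MS'`` (which
    includes SM) or ``'any'``.
    """
    if class_filter not in ("MM", "MS", "any"):
        raise ValueError("class_filter must be MM, MS or any")
    sel = (range(traj.n_frames) if times is None
           else [traj.frame_index_at(t) for t in times])
    out = []
    for idx in sel:
        bonds = detect_hbonds(traj.frame_model(idx), cutoffs=cutoffs)
        if class_filter == "MM":
            bonds = [b for b in bonds if b.hb_class == "MM"]
        elif class_filter == "MS":
            bonds = [b for b in bonds if b.hb_class in ("MS", "SM")]
        out.append((float(traj.times[idx]), len(bonds), bonds))
    return out


def classify_conformation(frame: StructureModel,
                          cutoffs: Cutoffs | None = None) -> str:
    """``'turn'`` iff the frame holds a backbone CO(i)->NH(i+3) or
    CO(i)->NH(i+4) main-chain H-bond, else ``'extended'``.

    The i/i+3(4) offsets are sequence positions in the same chain; the
    donor is the backbone amide N (or an amide cap), the acceptor the
    backbone carbonyl O.
    """
    for bond in detect_hbonds(frame, cutoffs=cutoffs):
        if bond.hb_class != "MM":
            continue
        if bond.atoms_a[0] != "N" or bond.atoms_b[0] not in ("O", "O1"):
            continue
        if bond.res_a.chain_id != bond.res_b.chain_id:
            continue
        if bond.res_a.seq_num - bond.res_b.seq_num in (3, 4):
            return "turn"
    return "extended"


@dataclass
class TrajectorySummary:
    """All descriptor series for one trajectory; lengths in nm with Å
    retained, times in ns."""
    times: np.ndarray
    rmsd_nm: np.ndarray
    rmsd_angstrom: np.ndarray
    rmsf_nm: np.ndarray
    rmsf_angstrom: np.ndarray
    rg_nm: np.ndarray
    rg_angstrom: np.ndarray
    residue_labels: list[str]
    hbond_counts: dict[float, int] = field(default_factory=dict)
    conformation: dict[float, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "times_ns": self.times.tolist(),
            "rmsd_nm": np.round(self.rmsd_nm, 6).tolist(),
            "rg_nm": np.round(self.rg_nm, 6).tolist(),
            "rmsf_nm": np.round(self.rmsf_nm, 6).tolist(),
            "residues": self.residue_labels,
            "hbond_counts": {str(t): c for t, c in self.hbond_counts.items()},
            "conformation": {str(t): c for t, c in self.conformation.items()},
        }


def summarize(traj: Trajectory, hbond_times: list[float] | None = None,
              cutoffs: Cutoffs | None = None,
              mass_weighted_rg: bool = True) -> TrajectorySummary:
    """Compute the full descriptor summary for a trajectory.

    ``hbond_times`` selects the times (ns) at which H-bonds are counted
    and the extended/turn conformation is called; defaults to first and
    last frame.
    """
    if hbond_times is None:
        hbond_times = [float(traj.times[0]), float(traj.times[-1])]
    rmsd_a = rmsd_series(traj)
    rmsf_a = rmsf(traj)
    rg_a = rg_series(traj, mass_weighted=mass_weighted_rg)
    hb = hbond_timeseries(traj, times=hbond_times, class_filter="MM",
                          cutoffs=cutoffs)
    conf = {}
    for t in hbond_times:
        idx = traj.frame_index_at(t)
        conf[float(traj.times[idx])] = classify_conformation(
            traj.frame_model(idx), cutoffs=cutoffs)
    return TrajectorySummary(
        times=traj.times.copy(),
        rmsd_nm=rmsd_a / 10.0, rmsd_angstrom=rmsd_a,
        rmsf_nm=rmsf_a / 10.0, rmsf_angstrom=rmsf_a,
        rg_nm=rg_a / 10.0, rg_angstrom=rg_a,
        residue_labels=[r.label for r in traj.topology.residues()],
        hbond_counts={t: n for t, n, _ in hb},
        conformation=conf)
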