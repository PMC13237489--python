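"""Hydrophobic contact occupancy from coordinate trajectories.

Post-processes snapshot trajectories (multi-model PDB or annotated XYZ)
into per-residue-pair contact occupancies and a trajectory-level exact
permutation test.  A contact is a residue pair whose closest heavy-atom
distance is at or below 0.45 nm; partner residues are the hydrophobic
residues outside the helix of interest that come within 0.60 nm of helix
heavy atoms in the first frame of each reference replicate (union over
replicates, so the same set is applied to both compared systems).
Distances are alignment-invariant, so no trajectory fitting is required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import false_discovery_control

logger = logging.getLogger(__name__)

HYDROPHOBIC = frozenset(
    {"ALA", "VAL", "ILE", "LEU", "MET", "PHE", "TYR", "TRP", "PRO"})

__all__ = [
    "HYDROPHOBIC",
    "ContactSpec",
    "TrajectoryFrames",
    "OccupancyTable",
    "load_trajectory",
    "write_multimodel_pdb",
    "hydrophobic_in_helix",
    "select_partner_set",
    "contact_occupancy",
    "occupancy_delta",
    "exact_permutation_test",
    "pairwise_permutation_tests",
]


@dataclass(frozen=True)
class ContactSpec:
    hydrophobic: frozenset = HYDROPHOBIC
    helix_range: tuple[int, int] = (124, 134)
    partner_cutoff: float = 0.60   # nm
    contact_cutoff: float = 0.45   # nm

    def __post_init__(self):
        if self.contact_cutoff > self.partner_cutoff:
            raise ValueError("contact_cutoff must be <= partner_cutoff")

    def helix_residues(self, resids) -> list[int]:
        lo, hi = self.helix_range
        return [r for r in resids if lo <= r <= hi]


@dataclass
class TrajectoryFrames:
    """One replicate: per-frame residue -> heavy-atom coordinates in nm."""

    system: str
    replicate_id: int
    resnames: dict[int, str]
    frames: list[dict[int, np.ndarray]]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a replicate needs at least one frame")
        resset = set(self.frames[0])
        for i, f in enumerate(self.frames):
            if set(f) != resset:
                raise ValueError(f"frame {i} has a different residue set")
            for coords in f.values():
                if not np.all(np.isfinite(coords)):
                    raise ValueError("non-finite coordinates")


def _is_heavy(name: str) -> bool:
    return not name.lstrip("0123456789").upper().startswith("H")


def load_trajectory(path, system: str = "", replicate_id: int = 0
                    ) -> TrajectoryFrames:
    """Read a multi-model PDB (via MDAnalysis; coordinates converted
    Angstrom -> nm) or an XYZ file whose atom-name column is
    ``<RESNAME><RESID>`` (e.g. ``LEU160``); hydrogens are dropped."""
    path = str(path)
    if path.endswith(".xyz"):
        return _load_xyz(path, system, replicate_id)
    import MDAnalysis as mda
    u = mda.Universe(path)
    heavy = u.select_atoms(
        "not name H* and not name 1H* and not name 2H* and not name 3H*")
    resnames = {int(r.resid): str(r.resname) for r in heavy.residues}
    frames = []
    for _ in u.trajectory:
        frame = {}
        for r in heavy.residues:
            frame[int(r.resid)] = r.atoms.positions.astype(float) / 10.0
        frames.append(frame)
    return TrajectoryFrames(system, replicate_id, resnames, frames)


def _load_xyz(path, system, replicate_id) -> TrajectoryFrames:
    frames, resnames = [], {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        atoms: dict[int, list] = {}
        for line in lines[i + 2:i + 2 + n]:
            name, x, y, z = line.split()
            resname, resid = name[:3], int(name[3:])
            resnames[resid] = resname
            atoms.setdefault(resid, []).append([float(x), float(y), float(z)])
        frames.append({rid: np.array(c) for rid, c in atoms.items()})
        i += 2 + n
    return TrajectoryFrames(system, replicate_id, resnames, frames)


def write_multimodel_pdb(traj: TrajectoryFrames, path) -> None:
    """Write frames as PDB MODEL records (nm -> Angstrom); atoms named C1.."""
    with open(path, "w") as fh:
        for mi, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            serial = 1
            for resid in sorted(frame):
                for ai, (x, y, z) in enumerate(frame[resid] * 10.0, start=1):
                    name = f"C{ai}"
                    fh.write(
                        f"ATOM  {serial:5d} {name:<4s} {traj.resnames[resid]:>3s}"
                        f" A{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"  1.00  0.00           C\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def hydrophobic_in_helix(traj: TrajectoryFrames,
                         spec: ContactSpec = ContactSpec()) -> list[int]:
    return [r for r in spec.helix_residues(traj.resnames)
            if traj.resnames[r] in spec.hydrophobic]


def select_partner_set(reference_trajectories,
                       spec: ContactSpec = ContactSpec()) -> set[int]:
    """Hydrophobic residues outside the helix within ``partner_cutoff`` of
    helix heavy atoms in the first frame of each reference replicate
    (union)."""
    partners: set[int] = set()
    for traj in reference_trajectories:
        frame = traj.frames[0]
        if not frame:
            raise ValueError("empty first frame")
        helix = spec.helix_residues(frame)
        helix_atoms = np.vstack([frame[r] for r in helix])
        for resid, coords in frame.items():
            if resid in helix or traj.resnames[resid] not in spec.hydrophobic:
                continue
            if _min_dist(coords, helix_atoms) <= spec.partner_cutoff:
                partners.add(resid)
    return partners


@dataclass
class OccupancyTable:
    """Per helix-partner pair, per replicate contact occupancies."""

    table: pd.DataFrame            # helix_res, partner_res, replicate, occupancy
    framewise_counts: list[int]    # total contacts per frame, pooled replicates
    system: str = ""

    def replicate_means(self) -> pd.Series:
        """Mean occupancy over pairs, one value per replicate."""
        return self.table.groupby("replicate").occupancy.mean()

    def pair_means(self) -> pd.Series:
        """Mean occupancy over replicates, one value per pair."""
        return self.table.groupby(["helix_res", "partner_res"]).occupancy.mean()

    def pair_replicates(self, helix_res: int, partner_res: int) -> np.ndarray:
        sel = self.table[(self.table.helix_res == helix_res)
                         & (self.table.partner_res == partner_res)]
        return sel.sort_values("replicate").occupancy.to_numpy()


def contact_occupancy(trajectories, helix_residues, partner_set,
                      spec: ContactSpec = ContactSpec()) -> OccupancyTable:
    """Occupancy of every helix-partner pair per replicate, plus pooled
    frame-wise total contact counts."""
    partner_set = sorted(partner_set)
    if not partner_set:
        raise ValueError("partner set is empty")
    rows = []
    framewise: list[int] = []
    system = ""
    for traj in trajectories:
        system = traj.system
        if not traj.frames:
            raise ValueError("replicate with zero frames")
        nf = len(traj.frames)
        hits = {(h, p): 0 for h in helix_residues for p in partner_set}
        for frame in traj.frames:
            total = 0
            for h in helix_residues:
                for p in partner_set:
                    if _min_dist(frame[h], frame[p]) <= spec.contact_cutoff:
                        hits[(h, p)] += 1
                        total += 1
            framewise.append(total)
        for (h, p), c in hits.items():
            rows.append({"helix_res": h, "partner_res": p,
                         "replicate": traj.replicate_id, "occupancy": c / nf})
    return OccupancyTable(table=pd.DataFrame(rows),
                          framewise_counts=framewise, system=system)


def occupancy_delta(mean_a: float, mean_b: float) -> tuple[float, float]:
    """(absolute delta, percent change) of system-b minus system-a means."""
    delta = mean_b - mean_a
    return delta, 100.0 * delta / mean_a if mean_a else math.nan


def exact_permutation_test(group_a, group_b) -> tuple[float, float]:
    """Exact two-sided permutation test on replicate-level means.

    Enumerates all C(n_a + n_b, n_a) relabelings (252 for 5 + 5); the
    observed relabeling is counted in the numerator, so the smallest
    attainable p is 1 / C(n, n_a).
    Returns (delta = mean(b) - mean(a), p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    obs = b.mean() - a.mean()
    count, total = 0, 0
    seen = set()
    for subset in combinations(range(n), na):
        if subset in seen:  # guard against duplicate enumeration
            raise RuntimeError("duplicate relabeling enumerated")
        seen.add(subset)
        mask = np.zeros(n, dtype=bool)
        mask[list(subset)] = True
        delta = pooled[~mask].mean() - pooled[mask].mean()
        if abs(delta) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return float(obs), count / total


def pairwise_permutation_tests(occ_a: OccupancyTable, occ_b: OccupancyTable
                               ) -> pd.DataFrame:
    """Per-pair exact permutation tests with Benjamini-Hochberg correction
    (secondary to the trajectory-level test)."""
    rows = []
    pairs = occ_a.table[["helix_res", "partner_res"]].drop_duplicates()
    for _, (h, p) in pairs.iterrows():
        ra = occ_a.pair_replicates(h, p)
        rb = occ_b.pair_replicates(h, p)
        delta, pval = exact_permutation_test(ra, rb)
        rows.append({"helix_res": int(h), "partner_res": int(p),
                     "delta": delta, "p": pval})
    df = pd.DataFrame(rows)
    df["q"] = false_discovery_control(df.p, method="bh")
    return df
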