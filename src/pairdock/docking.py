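"""Exhaustive rigid-body docking over receptor potential grids.

For every sampled rotation the ligand (rotated about its center of mass) is
swept over a translation lattice anchored at the grid origin.  The sweep is
evaluated as a cross-correlation between the receptor potential grids and a
trilinearly-spread ligand-atom density, computed with cached FFTs; this is
numerically identical to trilinear grid scoring at every lattice point.  The
best translation per rotation is retained and the per-rotation winners are
merged into a globally ranked solution list (lower score = better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfftn, next_fast_len, rfftn
from scipy.spatial.transform import Rotation

from .errors import ConstraintError, ValidationError
from .potentials import PairPotentialSet
from .scoring import DEFAULT_SPACING, PotentialGrid, build_grids
from .structure import Pose, TypedStructure, apply_pose, center_of_mass

# Sample-count constant of the rotation lattice: N = ceil(C / resolution^3)
# (resolution in radians).  Calibrated so that a 5.6 degree resolution gives
# ~70k rotations — the order exhaustive rigid docking searches use at that
# resolution — dense enough that the covering radius stays below the
# nominal resolution.
_ROTATION_BUDGET = 65.0

# Super-Fibonacci irrationals (Alexa 2022).
_PHI = math.sqrt(2.0)
_PSI = 1.533751168755204288118041


def generate_rotations(resolution_deg: float) -> Rotation:
    """Deterministic near-uniform covering of SO(3).

    Quaternions follow a super-Fibonacci spiral; the whole set is rotated so
    its first element is the identity (the metric is bi-invariant, so the
    covering radius is unchanged).  Every rotation of SO(3) lies within
    ``resolution_deg`` (angular distance) of some sample.
    """
    if resolution_deg <= 0 or resolution_deg > 180:
        raise ValidationError("rotational resolution must be in (0, 180] degrees")
    delta = math.radians(resolution_deg)
    n = max(2, math.ceil(_ROTATION_BUDGET / delta ** 3))
    i = np.arange(n) + 0.5
    t = i / n
    d = 2 * np.pi * i
    r, big_r = np.sqrt(t), np.sqrt(1.0 - t)
    alpha, beta = d / _PHI, d / _PSI
    quats = np.column_stack([
        r * np.sin(alpha), r * np.cos(alpha),
        big_r * np.sin(beta), big_r * np.cos(beta),
    ])  # scipy order (x, y, z, w)
    rots = Rotation.from_quat(quats)
    return rots[0].inv() * rots  # first sample -> identity


@dataclass(frozen=True)
class SearchSpec:
    """Search resolution and optional translational restriction."""

    rotational_resolution: float = 5.6  # degrees
    translational_step: float = DEFAULT_SPACING  # A
    restriction: tuple | None = None  # (center 3-vector, radius A)
    keep_per_rotation: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.rotational_resolution <= 0 or self.translational_step <= 0:
            raise ValidationError("search resolutions must be positive")
        if self.restriction is not None:
            center, radius = self.restriction
            if radius <= 0:
                raise ValidationError("restriction radius must be positive")


@dataclass
class Solution:
    pose: Pose
    score: float
    rank: int
    cluster_id: int = -1


@dataclass
class SolutionList:
    solutions: list[Solution]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def __getitem__(self, i):
        return self.solutions[i]


def dock(receptor: TypedStructure, ligand: TypedStructure, p: PairPotentialSet,
         spec: SearchSpec | None = None,
         grids: list[PotentialGrid] | None = None) -> SolutionList:
    """Exhaustive rigid-body search of ligand poses over the receptor.

    The translation lattice coincides with the grid nodes; the pose placing
    the rotated ligand's center of mass at lattice point ``x`` is
    ``Pose(R, x - R @ com)``.  With a restriction sphere only lattice points
    inside the sphere are scanned.  Deterministic for a fixed spec.
    """
    if spec is None:
        spec = SearchSpec()
    if grids is None:
        grids = build_grids(receptor, p, spacing=spec.translational_step)
    step = grids[0].spacing
    origin = grids[0].origin
    dims = np.array(grids[0].values.shape)
    by_type = {g.atom_type: g.values for g in grids}

    com = center_of_mass(ligand)
    local = ligand.coords - com
    lig_types = [str(t) for t in ligand.atom_type]
    present = sorted(set(lig_types))
    for t in present:
        if t not in by_type:
            raise ValidationError(f"no grid for ligand atom type {t!r}")

    # translation-lattice mask
    if spec.restriction is not None:
        center, radius = spec.restriction
        center = np.asarray(center, dtype=float)
        axes = [origin[k] + np.arange(dims[k]) * step for k in range(3)]
        dx = [axes[k] - center[k] for k in range(3)]
        mask = (dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2
                + dx[2][None, None, :] ** 2) <= radius ** 2
        if not mask.any():
            raise ValidationError("restriction sphere is disjoint from the grid box")
    else:
        mask = np.ones(tuple(dims), dtype=bool)

    # fixed-size ligand density support so receptor FFTs can be cached
    reach = int(np.ceil(np.max(np.linalg.norm(local, axis=1)) / step)) + 1 if len(local) else 1
    ksize = 2 * reach + 1
    kmin = -reach
    fshape = tuple(next_fast_len(int(dims[k]) + ksize - 1) for k in range(3))
    grid_fts = {t: rfftn(by_type[t], fshape) for t in present}
    type_rows = {t: np.array([i for i, lt in enumerate(lig_types) if lt == t]) for t in present}

    rotations = generate_rotations(spec.rotational_resolution)
    rot_mats = rotations.as_matrix()
    slc = tuple(slice(ksize - 1 + kmin, ksize - 1 + kmin + int(dims[k])) for k in range(3))

    raw: list[tuple[float, int, tuple[int, int, int]]] = []
    corners = np.array([[(c >> b) & 1 for b in range(3)] for c in range(8)])
    for ri in range(len(rot_mats)):
        q = local @ rot_mats[ri].T
        u = q / step - kmin
        base = np.floor(u).astype(int)
        frac = u - base
        acc = None
        for t in present:
            rows = type_rows[t]
            dens = np.zeros((ksize, ksize, ksize))
            for c in corners:
                w = np.prod(np.where(c == 1, frac[rows], 1.0 - frac[rows]), axis=1)
                idx = base[rows] + c
                np.add.at(dens, (idx[:, 0], idx[:, 1], idx[:, 2]), w)
            ft = rfftn(dens[::-1, ::-1, ::-1], fshape) * grid_fts[t]
            acc = ft if acc is None else acc + ft
        conv = irfftn(acc, fshape)[slc]
        scores = np.where(mask, conv, np.inf)
        k = min(spec.keep_per_rotation, scores.size)
        flat = scores.ravel()
        if k == 1:
            picks = [int(np.argmin(flat))]
        else:
            part = np.argpartition(flat, k - 1)[:k]
            picks = sorted(part, key=lambda ix: (flat[ix], ix))
        for ix in picks:
            if not np.isfinite(flat[ix]):
                continue
            raw.append((float(flat[ix]), ri, np.unravel_index(ix, scores.shape)))

    order = sorted(range(len(raw)), key=lambda i: (raw[i][0], i))
    solutions = []
    for rank, i in enumerate(order, start=1):
        score, ri, j = raw[i]
        node = origin + np.array(j) * step
        pose = Pose(rot_mats[ri], node - rot_mats[ri] @ com)
        solutions.append(Solution(pose=pose, score=score, rank=rank))
    return SolutionList(solutions, metadata={
        "rotational_resolution": spec.rotational_resolution,
        "translational_step": step,
        "n_rotations": len(rot_mats),
        "restriction": spec.restriction,
    })


# ---------------------------------------------------------------------------
# clustering (greedy leader; kclust-style stand-in validated by a brute-force
# oracle in the test suite)


def cluster_poses(coords_list: list[np.ndarray], threshold: float) -> np.ndarray:
    """Greedy leader clustering by coordinate rmsd (no superposition).

    Members are visited in the given order; each joins the first earlier
    leader within the threshold, otherwise it becomes a new leader.
    """
    labels = np.full(len(coords_list), -1, dtype=int)
    leaders: list[int] = []
    for i, coords in enumerate(coords_list):
        for li, leader in enumerate(leaders):
            d = coords - coords_list[leader]
            if np.sqrt(np.mean(np.sum(d * d, axis=1))) <= threshold:
                labels[i] = li
                break
        else:
            labels[i] = len(leaders)
            leaders.append(i)
    return labels


def cluster_solutions(solutions: SolutionList, ligand: TypedStructure,
                      threshold: float, order_by: str = "score",
                      selection=None) -> SolutionList:
    """Cluster a ranked solution list by ligand rmsd between poses.

    Solutions are visited in rank order, so every cluster's leader is its
    best-scored member (the representative).  Clusters are ordered by
    representative score (docking protocol) or by descending size (decoy
    protocol); the returned list is re-ranked with representatives first.
    """
    if order_by not in ("score", "size"):
        raise ValidationError(f"order_by must be 'score' or 'size', got {order_by!r}")
    if len(solutions) == 0:
        return SolutionList([], dict(solutions.metadata))
    from .structure import selection_mask
    msel = selection_mask(ligand, selection) if selection is not None else None
    base = ligand.coords if msel is None else ligand.coords[msel]
    coords = [sol.pose.apply(base) for sol in solutions]
    labels = cluster_poses(coords, threshold)
    n_clusters = labels.max() + 1
    members = [np.flatnonzero(labels == c) for c in range(n_clusters)]
    if order_by == "size":
        cluster_order = sorted(range(n_clusters),
                               key=lambda c: (-len(members[c]), members[c][0]))
    else:
        cluster_order = sorted(range(n_clusters),
                               key=lambda c: (solutions[members[c][0]].score, members[c][0]))
    out: list[Solution] = []
    for new_cid, c in enumerate(cluster_order):
        for i in members[c]:
            out.append(replace(solutions[int(i)], cluster_id=new_cid))
    for rank, sol in enumerate(out, start=1):
        sol.rank = rank
    meta = dict(solutions.metadata)
    meta["cluster_threshold"] = threshold
    meta["cluster_order"] = order_by
    return SolutionList(out, meta)


def cluster_representatives(clustered: SolutionList) -> SolutionList:
    """First (best-scored) member of each cluster, in cluster order."""
    seen: set[int] = set()
    reps = []
    for sol in clustered:
        if sol.cluster_id not in seen:
            seen.add(sol.cluster_id)
            reps.append(replace(sol))
    for rank, sol in enumerate(reps, start=1):
        sol.rank = rank
    return SolutionList(reps, dict(clustered.metadata))


# ---------------------------------------------------------------------------
# knowledge-driven search helpers


def pick_reference_points(receptor: TypedStructure, interface_hint, n: int,
                          seed: int, max_distance: float = 5.0,
                          min_separation: float = 5.0,
                          max_retries: int = 5000) -> np.ndarray:
    """Random reference points near hinted interface residues.

    Each point lies within ``max_distance`` of some hint-residue atom and at
    least ``min_separation`` from every other returned point; reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValidationError("need at least one reference point")
    hint = {(str(c), int(r)) for c, r in interface_hint}
    mask = np.array([
        (str(receptor.chain[i]), int(receptor.residue_number[i])) in hint
        for i in range(len(receptor))
    ])
    anchors = receptor.coords[mask]
    if len(anchors) == 0:
        raise ValidationError("no receptor atoms match the interface hint")
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        if tries >= max_retries:
            raise ConstraintError(
                f"could not place {n} reference points with {min_separation} A separation"
            )
        tries += 1
        anchor = anchors[rng.integers(len(anchors))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = anchor + direction * rng.uniform(0.0, max_distance * 0.98)
        if all(np.linalg.norm(cand - q) >= min_separation for q in points):
            points.append(cand)
    return np.array(points)


def rerank_by_tyr(solutions: SolutionList, receptor: TypedStructure,
                  ligand: TypedStructure, antibody: str = "ligand",
                  top_n: int = 100, cutoff: float = 10.0) -> SolutionList:
    """Reorder the top solutions by antibody interface-Tyr abundance.

    The first ``top_n`` solutions are sorted by descending count of Tyr
    residues of the antibody partner inside the 10 A interface of the posed
    complex; ties keep their original order, and the remainder of the list is
    untouched.
    """
    if antibody not in ("receptor", "ligand"):
        raise ValidationError(f"unknown partner tag {antibody!r}")
    from .evaluation import interface_residues
    head = list(solutions)[:top_n]
    tail = list(solutions)[top_n:]

    def tyr_count(sol: Solution) -> int:
        posed = apply_pose(ligand, sol.pose)
        rec_set, lig_set = interface_residues(receptor, posed, cutoff=cutoff)
        partner, struct = (rec_set, receptor) if antibody == "receptor" else (lig_set, posed)
        resname = {}
        for i in range(len(struct)):
            resname[(str(struct.chain[i]), int(struct.residue_number[i]),
                     str(struct.insertion_code[i]))] = str(struct.residue_name[i])
        return sum(1 for key in partner if resname.get(key) == "TYR")

    counts = [tyr_count(s) for s in head]
    order = sorted(range(len(head)), key=lambda i: (-counts[i], i))
    out = [replace(head[i]) for i in order] + [replace(s) for s in tail]
    for rank, sol in enumerate(out, start=1):
        sol.rank = rank
    return SolutionList(out, dict(solutions.metadata))


# ---------------------------------------------------------------------------
# solutions file (tab-separated; exact round trip)


def save_solutions(solutions: SolutionList, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tscore\tqw\tqx\tqy\tqz\ttx\tty\ttz\tcluster_id\n")
        for sol in solutions:
            q = sol.pose.quaternion()
            t = sol.pose.translation
            fh.write(
                f"{sol.rank}\t{sol.score:.17g}\t"
                f"{q[0]:.17g}\t{q[1]:.17g}\t{q[2]:.17g}\t{q[3]:.17g}\t"
                f"{t[0]:.17g}\t{t[1]:.17g}\t{t[2]:.17g}\t{sol.cluster_id}\n"
            )


def load_solutions(path) -> SolutionList:
    sols = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("rank\t"):
            raise ValidationError(f"{path}: not a solutions file")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rank, score = int(parts[0]), float(parts[1])
            quat = [float(x) for x in parts[2:6]]
            trans = [float(x) for x in parts[6:9]]
            cid = int(parts[9])
            sols.append(Solution(Pose.from_quaternion(quat, trans), score, rank, cid))
    return SolutionList(sols)
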