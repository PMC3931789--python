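"""Scoring of protein-protein configurations with the pair potentials.

Two routes are provided: a direct double sum over inter-partner atom pairs
within the 5 A cutoff, and a fast path via precomputed receptor potential
grids (one rectangular scalar field per ligand atom type).  Lower dW is more
favorable; rankings sort ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .potentials import MAX_DISTANCE, PairPotentialSet
from .structure import Pose, TypedStructure, apply_pose, center_of_mass

DEFAULT_SPACING = 1.0  # A; matches the translational search step


@dataclass(frozen=True)
class Score:
    """A docking score: dW plus the number of contributing atom pairs."""

    value: float
    n_pairs: int

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValidationError("score must be finite")


@dataclass
class PotentialGrid:
    """Receptor potential field for one ligand atom type.

    ``values[i, j, k]`` holds the summed dW of placing a probe atom of
    ``atom_type`` at node ``origin + (i, j, k) * spacing`` (x-fastest when
    flattened in Fortran order).  The box is centered at the receptor center
    of mass and leaves a 5 A margin beyond the receptor on every face, so an
    atom outside the box is outside the interaction shell and scores zero.
    """

    atom_type: str
    origin: np.ndarray
    spacing: float
    values: np.ndarray  # shape (nx, ny, nz)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def node_coords(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny*nz, 3), x varying fastest."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3, order="F")
        return self.origin + idx * self.spacing


def score_direct(receptor: TypedStructure, ligand: TypedStructure,
                 p: PairPotentialSet) -> Score:
    """Sum dW over all inter-partner heavy-atom pairs closer than 5 A."""
    for part, tag in ((receptor, "receptor"), (ligand, "ligand")):
        if not part.is_typed:
            raise ValidationError(f"{tag} has untyped atoms; assign atom types first")
    ti_r = np.array([p.type_index(t) for t in receptor.atom_type])
    ti_l = np.array([p.type_index(t) for t in ligand.atom_type])
    bw, n_bins = p.bin_width, p.values.shape[2]
    total, n_pairs = 0.0, 0
    neigh = cKDTree(receptor.coords).query_ball_tree(cKDTree(ligand.coords), MAX_DISTANCE)
    for ir, hits in enumerate(neigh):
        if not hits:
            continue
        d = np.linalg.norm(ligand.coords[hits] - receptor.coords[ir], axis=1)
        inside = d < MAX_DISTANCE
        if not np.any(inside):
            continue
        bins = np.minimum((d[inside] / bw).astype(int), n_bins - 1)
        total += float(p.values[ti_r[ir], ti_l[np.asarray(hits)[inside]], bins].sum())
        n_pairs += int(inside.sum())
    if n_pairs == 0:
        return Score(0.0, 0)
    return Score(total, n_pairs)


def build_grids(receptor: TypedStructure, p: PairPotentialSet,
                spacing: float = DEFAULT_SPACING) -> list[PotentialGrid]:
    """Precompute one potential grid per atom type of the alphabet.

    Each node accumulates dW(receptor type, grid type, node-atom distance)
    over receptor atoms within 5 A of the node.
    """
    if spacing <= 0:
        raise ValidationError("grid spacing must be positive")
    if not receptor.is_typed:
        raise ValidationError("receptor has untyped atoms")
    com = center_of_mass(receptor)
    lo = receptor.coords.min(axis=0) - MAX_DISTANCE
    hi = receptor.coords.max(axis=0) + MAX_DISTANCE
    half = np.maximum(hi - com, com - lo)  # box centered at the center of mass
    dims = (np.ceil(2 * half / spacing).astype(int) + 1)
    origin = com - (dims - 1) * spacing / 2.0

    nx, ny, nz = (int(d) for d in dims)
    axes = [origin[k] + np.arange(dims[k]) * spacing for k in range(3)]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    node_tree = cKDTree(nodes)

    ti_r = np.array([p.type_index(t) for t in receptor.atom_type])
    bw, n_bins = p.bin_width, p.values.shape[2]
    fields = np.zeros((len(p.types), len(nodes)))
    for ia in range(len(receptor)):
        hits = node_tree.query_ball_point(receptor.coords[ia], MAX_DISTANCE)
        if not hits:
            continue
        hits = np.asarray(hits)
        d = np.linalg.norm(nodes[hits] - receptor.coords[ia], axis=1)
        inside = d < MAX_DISTANCE
        hits, d = hits[inside], d[inside]
        bins = np.minimum((d / bw).astype(int), n_bins - 1)
        for tg in range(len(p.types)):
            np.add.at(fields[tg], hits, p.values[ti_r[ia], tg, bins])
    return [
        PotentialGrid(p.types[tg], origin.copy(), float(spacing),
                      fields[tg].reshape(nx, ny, nz))
        for tg in range(len(p.types))
    ]


def _trilinear(values: np.ndarray, u: np.ndarray) -> float:
    """Trilinear interpolation at fractional index u (assumed in bounds)."""
    base = np.floor(u).astype(int)
    base = np.minimum(base, np.array(values.shape) - 2)
    base = np.maximum(base, 0)
    f = u - base
    out = 0.0
    for corner in range(8):
        off = np.array([(corner >> k) & 1 for k in range(3)])
        w = np.prod(np.where(off == 1, f, 1.0 - f))
        idx = base + off
        out += w * values[idx[0], idx[1], idx[2]]
    return float(out)


def score_on_grid(grids: list[PotentialGrid], ligand: TypedStructure,
                  pose: Pose | None = None,
                  interpolation: str = "trilinear") -> Score:
    """Score a posed ligand against precomputed receptor grids.

    Each ligand atom samples the grid matching its type (trilinear by
    default; ``"nearest"`` reproduces node values exactly).  Atoms posed
    outside the grid box contribute zero and are counted in ``n_pairs`` only
    when inside.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if not ligand.is_typed:
        raise ValidationError("ligand has untyped atoms")
    by_type = {g.atom_type: g for g in grids}
    posed = apply_pose(ligand, pose) if pose is not None else ligand
    total, n_inside = 0.0, 0
    for i in range(len(posed)):
        typ = str(posed.atom_type[i])
        grid = by_type.get(typ)
        if grid is None:
            raise ValidationError(f"no grid for atom type {typ!r}")
        u = (posed.coords[i] - grid.origin) / grid.spacing
        dims = np.array(grid.dims)
        if np.any(u < 0) or np.any(u > dims - 1):
            continue  # outside the box: beyond the interaction shell, scores 0
        n_inside += 1
        if interpolation == "nearest":
            idx = np.clip(np.rint(u).astype(int), 0, dims - 1)
            total += float(grid.values[idx[0], idx[1], idx[2]])
        else:
            total += _trilinear(grid.values, u)
    return Score(total, n_inside)


# ---------------------------------------------------------------------------
# grid persistence: .npz archive (compact) and a text export for small grids


def save_grids(grids: list[PotentialGrid], path) -> None:
    arrays = {}
    meta = []
    for k, g in enumerate(grids):
        arrays[f"values_{k}"] = g.values
        meta.append((g.atom_type, *g.origin, g.spacing))
    arrays["meta_types"] = np.array([m[0] for m in meta])
    arrays["meta_geom"] = np.array([m[1:] for m in meta], dtype=float)
    np.savez(path, **arrays)


def load_grids(path) -> list[PotentialGrid]:
    data = np.load(path, allow_pickle=False)
    types = data["meta_types"]
    geom = data["meta_geom"]
    return [
        PotentialGrid(str(types[k]), geom[k, :3].copy(), float(geom[k, 3]),
                      data[f"values_{k}"])
        for k in range(len(types))
    ]


def export_grid_text(grid: PotentialGrid, path) -> None:
    """Plain-text dump (header + one node value per line, x fastest)."""
    with open(path, "w") as fh:
        fh.write(f"#atom_type\t{grid.atom_type}\n")
        fh.write(f"#origin\t{grid.origin[0]:.17g}\t{grid.origin[1]:.17g}\t{grid.origin[2]:.17g}\n")
        fh.write(f"#spacing\t{grid.spacing:.17g}\n")
        fh.write(f"#dims\t{grid.dims[0]}\t{grid.dims[1]}\t{grid.dims[2]}\n")
        for v in grid.values.flatten(order="F"):
            fh.write(f"{v:.17g}\n")
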