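"""Deterministic synthetic fixtures: toy complexes, decoy ensembles and mini
knowledge bases.

Toy complexes are built from idealized residue templates (no backbone
realism — downstream code only assumes typed heavy atoms and distances).
The receptor is "molded" around the ligand: residue pods along a spherical
cap of directions slide inward until they sit at a prescribed gap from the
ligand surface, and a filler shell of glycine pods behind them gives the
wall thickness (excluded volume).  This guarantees an interface with many
contacts at a known distance, a clash floor, and strong orientational
discrimination (a rotated or penetrating ligand no longer fits the mold),
which is what rigid redocking fixtures need.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConstraintError, ValidationError
from .structure import (
    Pose,
    TypedStructure,
    apply_pose,
    assign_atom_types,
    center_of_mass,
    rmsd,
)

# Residue templates: local offsets from CA in the frame
# (x: side-chain/outward, y: chain tangent, z: normal).  Backbone first.
_BACKBONE = [("N", "N", (-0.45, -1.35, 0.05)), ("CA", "C", (0.0, 0.0, 0.0)),
             ("C", "C", (-0.45, 1.35, 0.05)), ("O", "O", (-1.0, 2.2, -0.6))]

_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (1.50, 0.10, 0.10))],
    "SER": [("CB", "C", (1.50, 0.10, 0.10)), ("OG", "O", (2.70, 0.60, 0.20))],
    "THR": [("CB", "C", (1.50, 0.10, 0.10)), ("OG1", "O", (2.60, 0.80, 0.30)),
            ("CG2", "C", (2.50, -0.90, -0.20))],
    "VAL": [("CB", "C", (1.50, 0.10, 0.10)), ("CG1", "C", (2.60, 0.90, 0.20)),
            ("CG2", "C", (2.55, -0.85, -0.30))],
    "LEU": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.90, 0.20, 0.10)),
            ("CD1", "C", (3.90, 1.00, 0.30)), ("CD2", "C", (3.85, -0.90, -0.20))],
    "ASP": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.95, 0.30, 0.10)),
            ("OD1", "O", (3.70, 1.20, 0.20)), ("OD2", "O", (3.65, -0.80, -0.30))],
    "ASN": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.95, 0.30, 0.10)),
            ("OD1", "O", (3.70, 1.20, 0.20)), ("ND2", "N", (3.65, -0.85, -0.25))],
    "GLU": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.90, 0.20, 0.10)),
            ("CD", "C", (4.30, 0.30, 0.10)), ("OE1", "O", (5.00, 1.20, 0.20)),
            ("OE2", "O", (5.00, -0.80, -0.30))],
    "LYS": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.90, 0.20, 0.10)),
            ("CD", "C", (4.30, 0.30, 0.10)), ("CE", "C", (5.70, 0.30, 0.15)),
            ("NZ", "N", (7.00, 0.40, 0.20))],
    "ARG": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.90, 0.20, 0.10)),
            ("CD", "C", (4.30, 0.30, 0.10)), ("NE", "N", (5.60, 0.25, 0.10)),
            ("CZ", "C", (6.90, 0.30, 0.10)), ("NH1", "N", (7.60, 1.30, 0.20)),
            ("NH2", "N", (7.60, -0.90, -0.30))],
    "PHE": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.95, 0.20, 0.10)),
            ("CD1", "C", (3.65, 1.30, 0.15)), ("CD2", "C", (3.65, -1.00, -0.10)),
            ("CE1", "C", (5.00, 1.30, 0.20)), ("CE2", "C", (5.00, -1.00, -0.15)),
            ("CZ", "C", (5.70, 0.10, 0.05))],
    "TYR": [("CB", "C", (1.50, 0.10, 0.10)), ("CG", "C", (2.95, 0.20, 0.10)),
            ("CD1", "C", (3.65, 1.30, 0.15)), ("CD2", "C", (3.65, -1.00, -0.10)),
            ("CE1", "C", (5.00, 1.30, 0.20)), ("CE2", "C", (5.00, -1.00, -0.15)),
            ("CZ", "C", (5.70, 0.10, 0.05)), ("OH", "O", (7.05, 0.15, 0.10))],
}

#: compact residues (short reach) and the full default palette
COMPACT_PALETTE = ("ALA", "SER", "THR", "VAL", "ASP", "ASN", "LEU")
DEFAULT_PALETTE = tuple(_SIDECHAINS)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    n_residues_receptor: int = 28
    n_residues_ligand: int = 6
    contact_target: int = 20  # minimum inter-chain atom pairs below 5 A
    gap: float = 3.5  # A: molded receptor-ligand surface separation
    rotation_scale: float = 25.0  # deg, decoy perturbations
    translation_scale: float = 20.0  # A, decoy perturbations
    n_decoys: int = 100
    receptor_palette: tuple = COMPACT_PALETTE
    ligand_palette: tuple = COMPACT_PALETTE
    backing: bool = True  # second residue layer: gives the receptor wall thickness
    seed: int = 0

    def __post_init__(self):
        if self.n_residues_receptor < 1 or self.n_residues_ligand < 1:
            raise ValidationError("chain sizes must be positive")
        if self.n_decoys < 1:
            raise ValidationError("n_decoys must be positive")


def _residue_atoms(resname: str, ca: np.ndarray, frame: np.ndarray,
                   rng: np.random.Generator, jitter: float):
    """Atom (name, element, coords) records for one residue pod."""
    out = []
    for name, element, off in _BACKBONE:
        pos = ca + frame @ np.asarray(off)
        out.append((name, element, pos))
    for name, element, off in _SIDECHAINS[resname]:
        pos = ca + frame @ np.asarray(off) + rng.uniform(-jitter, jitter, 3)
        out.append((name, element, pos))
    return out


def _build_structure(records, chain: str, provenance: str) -> TypedStructure:
    serial, names, resnames, chains, resnums, icodes, elements, coords = (
        [], [], [], [], [], [], [], [])
    s = 1
    for resnum, resname, atoms in records:
        for name, element, pos in atoms:
            serial.append(s)
            names.append(name)
            resnames.append(resname)
            chains.append(chain)
            resnums.append(resnum)
            icodes.append("")
            elements.append(element)
            coords.append(pos)
            s += 1
    st = TypedStructure(serial, names, resnames, chains, resnums, icodes,
                        elements, np.array(coords), provenance=provenance)
    return assign_atom_types(st)


def make_toy_complex(spec: FixtureSpec) -> tuple[TypedStructure, TypedStructure]:
    """A bound receptor/ligand pair with a molded, contact-rich interface.

    Guarantees: at least one inter-chain pair below 5 A (in fact at least
    ``contact_target``), no inter-chain pair below 2.0 A, receptor larger
    than ligand, identical bytes for identical specs.
    """
    rng = np.random.default_rng(spec.seed)

    # ligand: small helix of residue pods, side chains pointing outward
    lig_records = []
    lig_coords = []
    for i in range(spec.n_residues_ligand):
        theta = math.radians(100.0) * i
        ca = np.array([2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i])
        e_s = np.array([math.cos(theta), math.sin(theta), 0.0])
        e_t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        e_n = np.array([0.0, 0.0, 1.0])
        frame = np.column_stack([e_s, e_t, e_n])
        resname = spec.ligand_palette[rng.integers(len(spec.ligand_palette))]
        atoms = _residue_atoms(resname, ca, frame, rng, jitter=0.15)
        lig_records.append((i + 1, resname, atoms))
        lig_coords.extend(a[2] for a in atoms)
    lig_coords = np.asarray(lig_coords)
    centroid = lig_coords.mean(axis=0)
    lig_records = [
        (num, rn, [(n, e, p - centroid) for n, e, p in atoms])
        for num, rn, atoms in lig_records
    ]
    lig_coords = lig_coords - centroid

    # receptor contact layer: pods along directions of a spherical cap around
    # -x, each molded inward (side chains toward the ligand) to the gap
    n_rec = spec.n_residues_receptor
    wrap = math.radians(120.0)
    w = np.array([-1.0, 0.0, 0.0])  # cap axis: the receptor side
    i = np.arange(n_rec) + 0.5
    cos_cap = 1 - (1 - math.cos(wrap)) * i / n_rec
    azimuth = math.pi * (1 + 5 ** 0.5) * i
    sin_cap = np.sqrt(1 - cos_cap ** 2)
    # directions in a frame where w is the pole
    pole_dirs = np.column_stack([
        -cos_cap, sin_cap * np.cos(azimuth), sin_cap * np.sin(azimuth)])
    rec_records = []
    placed = 0
    for k in range(n_rec):
        u = pole_dirs[k]
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e_t = np.cross(u, ref)
        e_t /= np.linalg.norm(e_t)
        frame = np.column_stack([-u, e_t, np.cross(u, e_t)])
        resname = spec.receptor_palette[rng.integers(len(spec.receptor_palette))]
        local = _residue_atoms(resname, np.zeros(3), frame, rng, jitter=0.15)
        local_coords = np.array([a[2] for a in local])
        # slide the pod inward along u until it reaches the gap
        rho, atoms = 20.0, None
        while rho > 2.0:
            cand = local_coords + rho * u
            dmin = np.min(np.linalg.norm(
                cand[:, None, :] - lig_coords[None, :, :], axis=2))
            if dmin <= spec.gap + 0.1:
                atoms = [(n, e, c) for (n, e, _), c in zip(local, cand)]
                break
            rho -= 0.05
        if atoms is None:
            raise ConstraintError("receptor pod could not reach the ligand surface")
        placed += 1
        rec_records.append((placed, resname, atoms))

    if spec.backing:
        # filler shell behind the contact layer: excluded volume, as in a
        # packed protein core — penetrating poses collide with many atoms
        layer_coords = np.array([c for _, _, atoms in rec_records for _, _, c in atoms])
        grid_1d = np.arange(-16.0, 16.1, 3.4)
        for ix, x in enumerate(grid_1d):
            for iy, y in enumerate(grid_1d):
                for iz, z in enumerate(grid_1d):
                    site = np.array([x, y, z]) + rng.uniform(-0.4, 0.4, 3)
                    d_lig = np.min(np.linalg.norm(lig_coords - site, axis=1))
                    if not 4.8 <= d_lig <= 9.5:
                        continue
                    nrm = np.linalg.norm(site)
                    if nrm < 1e-6 or math.acos(np.clip(site @ w / nrm, -1, 1)) > wrap + 0.25:
                        continue
                    if np.min(np.linalg.norm(layer_coords - site, axis=1)) < 2.6:
                        continue
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
                    e_t = np.cross(axis, ref)
                    e_t /= np.linalg.norm(e_t)
                    frame = np.column_stack([axis, e_t, np.cross(axis, e_t)])
                    pod = _residue_atoms("GLY", site, frame, rng, jitter=0.15)
                    placed += 1
                    rec_records.append((placed, "GLY", pod))
                    layer_coords = np.vstack([layer_coords, [c for _, _, c in pod]])

    receptor = _build_structure(rec_records, "A", f"synthetic receptor seed={spec.seed}")
    ligand = _build_structure(lig_records, "B", f"synthetic ligand seed={spec.seed}")

    d = np.linalg.norm(
        receptor.coords[:, None, :] - ligand.coords[None, :, :], axis=2)
    if d.min() < 2.0:
        raise ConstraintError(f"clash floor violated: min inter-chain distance {d.min():.2f} A")
    n_contacts = int((d < 5.0).sum())
    if n_contacts < spec.contact_target:
        raise ConstraintError(
            f"only {n_contacts} inter-chain contacts < 5 A (target {spec.contact_target})"
        )
    return receptor, ligand


# ---------------------------------------------------------------------------
# decoys


@dataclass(frozen=True)
class Decoy:
    pose: Pose
    ligand_rmsd: float  # all-atom, no superposition; exact for the pose


def make_decoys(receptor: TypedStructure, ligand: TypedStructure,
                spec: FixtureSpec,
                rmsd_range: tuple[float, float] = (0.0, 20.0),
                clash_floor: float = 2.6) -> list[Decoy]:
    """Rigid ligand perturbations spanning near-native to far poses.

    Decoy i targets an rmsd ramped over ``rmsd_range`` (with jitter); the
    recorded rmsd is recomputed exactly from the perturbed coordinates.  The
    first decoy is the unperturbed native (rmsd 0).  Decoys emulate
    stereochemically correct (minimized) ensembles: perturbations driving
    any inter-partner atom pair below ``clash_floor`` are resampled, and as
    a last resort the ligand is backed out along the receptor-to-ligand
    axis until clash-free.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(spec.seed + 1)
    com = center_of_mass(ligand)
    escape = com - center_of_mass(receptor)
    escape /= np.linalg.norm(escape)
    lo, hi = rmsd_range
    decoys = [Decoy(Pose.identity(), 0.0)]

    def min_gap(pose):
        posed = apply_pose(ligand, pose)
        d = np.linalg.norm(
            receptor.coords[:, None, :] - posed.coords[None, :, :], axis=2)
        return float(d.min())

    for i in range(1, spec.n_decoys):
        t = i / max(1, spec.n_decoys - 1)
        target = lo + (hi - lo) * t * rng.uniform(0.85, 1.15)
        pose = None
        for _ in range(40):
            angle = math.radians(spec.rotation_scale) * t * rng.uniform(0.0, 1.0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(angle * axis).as_matrix()
            # rotation about the ligand center of mass
            pose_rot = Pose(rot, com - rot @ com)
            r_rot = rmsd(ligand, apply_pose(ligand, pose_rot))
            shift = math.sqrt(max(target ** 2 - r_rot ** 2, 0.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = Pose(rot, com - rot @ com + shift * direction)
            if min_gap(cand) >= clash_floor:
                pose = cand
                break
            last = cand
        if pose is None:
            # back the clashing candidate out along the escape axis
            pose = last
            while min_gap(pose) < clash_floor:
                pose = Pose(pose.rotation, pose.translation + 0.5 * escape)
        exact = rmsd(ligand, apply_pose(ligand, pose))
        decoys.append(Decoy(pose, exact))
    return decoys


# ---------------------------------------------------------------------------
# mini knowledge bases


def _stratified_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """Randomized stratified variates on (0, 1): one draw per stratum."""
    return (np.arange(size) + rng.uniform(size=size)) / size


def sample_law(law, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw inter-partner distances in (0, 5) A from a distance-law spec.

    Laws: ("uniform", lo, hi), ("gaussian", mu, sigma) truncated to (0, 5),
    or ("mixture", (w1, law1), (w2, law2), ...).

    Sampling is randomized-stratified through the inverse CDF: a synthetic
    knowledge base is meant to *embody* its distance law, so the empirical
    histogram tracks the law with O(1) per-bin deviation instead of the
    O(sqrt(n)) of iid draws, while staying a pure function of the seed.
    """
    kind = law[0]
    if kind == "uniform":
        _, lo, hi = law
        if not (0 <= lo < hi <= 5):
            raise ValidationError("uniform law must be supported on (0, 5) A")
        return lo + (hi - lo) * _stratified_uniform(rng, size)
    if kind == "gaussian":
        _, mu, sigma = law
        if not (0 < mu < 5 and sigma > 0):
            raise ValidationError("gaussian law must be centered in (0, 5) A")
        from scipy.stats import truncnorm
        a, b = (0.0 - mu) / sigma, (5.0 - mu) / sigma
        return truncnorm.ppf(_stratified_uniform(rng, size), a, b,
                             loc=mu, scale=sigma)
    if kind == "mixture":
        weights = np.array([w for w, _ in law[1:]], dtype=float)
        weights /= weights.sum()
        sizes = np.floor(weights * size).astype(int)
        for k in range(size - sizes.sum()):  # distribute the remainder
            sizes[k % len(sizes)] += 1
        parts = [sample_law(sub, rng, int(n))
                 for n, (_, sub) in zip(sizes, law[1:]) if n > 0]
        return rng.permutation(np.concatenate(parts))
    raise ValidationError(f"unknown distance law {law!r}")


# Representative (residue, atom) per type label, used to give knowledge-base
# atoms canonical identities.
_TYPE_REPRESENTATIVE = {
    "C.2": ("GLY", "C"), "C.3": ("ALA", "CB"), "C.ar": ("PHE", "CZ"),
    "N.3": ("LYS", "NZ"), "N.am": ("GLY", "N"), "N.ar": ("HIS", "ND1"),
    "N.pl3": ("ARG", "NH1"), "O.2": ("GLY", "O"), "O.3": ("SER", "OG"),
    "O.co2": ("ASP", "OD1"), "S.3": ("CYS", "SG"),
}

_TYPE_ELEMENT = {t: t[0] if t[0] != "S" else "S" for t in _TYPE_REPRESENTATIVE}


def make_knowledge_base(laws: dict, n_per_pair: int, seed: int,
                        pairs_per_complex: int = 500) -> list[tuple[TypedStructure, TypedStructure]]:
    """Typed complex pairs whose inter-partner distances follow given laws.

    ``laws`` maps unordered type pairs to distance-law specs.  Atom pairs are
    planted on a 12 A lattice so only the intended partner atoms fall within
    the 5 A counting shell; empirical histograms converge to the laws as
    ``n_per_pair`` grows.
    """
    rng = np.random.default_rng(seed)
    samples = []  # (type_a, type_b, distance)
    for (a, b), law in sorted(laws.items()):
        for d in sample_law(law, rng, n_per_pair):
            samples.append((a, b, float(d)))
    order = rng.permutation(len(samples))
    complexes = []
    for start in range(0, len(samples), pairs_per_complex):
        chunk = [samples[i] for i in order[start:start + pairs_per_complex]]
        rec = {"serial": [], "name": [], "resname": [], "resnum": [],
               "element": [], "coords": [], "type": []}
        lig = {k: [] for k in rec}
        side = math.ceil(len(chunk) ** (1 / 3))
        for idx, (a, b, d) in enumerate(chunk):
            ix, iy, iz = idx % side, (idx // side) % side, idx // side ** 2
            site = 12.0 * np.array([ix, iy, iz], dtype=float)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for part, typ, pos in ((rec, a, site), (lig, b, site + d * direction)):
                resname, atname = _TYPE_REPRESENTATIVE[typ]
                part["serial"].append(idx + 1)
                part["name"].append(atname)
                part["resname"].append(resname)
                part["resnum"].append(idx + 1)
                part["element"].append(_TYPE_ELEMENT[typ])
                part["coords"].append(pos)
                part["type"].append(typ)
        def build(part, chain):
            return TypedStructure(
                part["serial"], part["name"], part["resname"],
                [chain] * len(part["serial"]), part["resnum"],
                [""] * len(part["serial"]), part["element"],
                np.array(part["coords"]), part["type"],
                provenance=f"synthetic KB seed={seed}",
            )
        complexes.append((build(rec, "A"), build(lig, "B")))
    return complexes


def uniform_laws(types, lo: float = 0.5, hi: float = 5.0) -> dict:
    """One shared uniform law for every unordered pair of the given types."""
    laws = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            laws[(a, b)] = ("uniform", lo, hi)
    return laws


def contact_laws(types, mu: float = 3.6, sigma: float = 0.2,
                 background: float = 0.3, background_lo: float = 3.1) -> dict:
    """A shared contact law: Gaussian peak at ``mu`` over a uniform floor.

    The floor starts at ``background_lo`` — below typical heavy-atom contact
    distances the knowledge base holds no observations, so the derived
    potential turns positive there (pseudo-count regime), exactly like a
    real knowledge base.  Derived against a uniform reference this yields
    one broad attractive well per pair at the contact distance — the
    canonical shape for the redocking fixtures.
    """
    law = ("mixture",
           (1.0 - background, ("gaussian", mu, sigma)),
           (background, ("uniform", background_lo, 5.0)))
    laws = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            laws[(a, b)] = law
    return laws


def fixture_atom_types(*structures) -> tuple[str, ...]:
    """Sorted atom-type alphabet present in the given structures."""
    types: set[str] = set()
    for s in structures:
        types.update(str(t) for t in s.atom_type)
    return tuple(sorted(types))


def demo_workspace(outdir, seed: int = 0) -> dict:
    """Write a complete deterministic demo workspace.

    Runs the full pipeline at desk scale: toy complex -> mini knowledge
    base -> derived + repulsion-augmented potentials -> coarse rigid-body
    docking (clustered) -> decoy rescoring with funnel statistics.  All
    outputs are plain text; identical seeds give byte-identical files.
    """
    import json

    from . import docking as dk
    from . import evaluation as ev
    from . import potentials as pp
    from . import scoring as sc
    from .structure import write_pdb

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(seed=seed)
    receptor, ligand = make_toy_complex(spec)
    paths = {}
    for name, st in (("receptor", receptor), ("ligand", ligand)):
        paths[name] = out / f"{name}.pdb"
        write_pdb(st, paths[name])

    types = fixture_atom_types(receptor, ligand)
    pot = make_redock_potentials(types, seed=seed + 1)
    paths["potentials"] = out / "potentials.tsv"
    pp.save_potentials(pot, paths["potentials"])

    sols = dk.dock(receptor, ligand, pot,
                   dk.SearchSpec(rotational_resolution=40.0, translational_step=1.0))
    clustered = dk.cluster_solutions(sols, ligand, threshold=5.0,
                                     order_by="score", selection="backbone")
    paths["solutions"] = out / "solutions.tsv"
    dk.save_solutions(dk.cluster_representatives(clustered), paths["solutions"])

    decoys = make_decoys(receptor, ligand, spec)
    scores = [sc.score_direct(receptor, apply_pose(ligand, d.pose), pot).value
              for d in decoys]
    rmsds = [d.ligand_rmsd for d in decoys]
    order = sorted(range(len(decoys)), key=lambda i: (scores[i], i))
    funnel = ev.funnel_spearman(scores, rmsds)
    top_pose = clustered[0].pose
    quality = ev.assess_quality((receptor, apply_pose(ligand, top_pose)),
                                (receptor, ligand))
    report = {
        "seed": seed,
        "native_score": sc.score_direct(receptor, ligand, pot).value,
        "n_solutions": len(clustered),
        "top_solution_score": clustered[0].score,
        "top_solution_class": quality.quality_class,
        "funnel_spearman": funnel.spearman_rs,
        "decoy_rank1_rmsd": rmsds[order[0]],
    }
    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return paths


# Height-to-well-depth ratio of the published repulsion parameterization
# (height 280000 against wells of order -4300).  Potentials derived from the
# mini knowledge bases have wells of order 1, so the redocking fixtures scale
# the repulsion height by the same ratio to keep the two regimes consistent.
REPULSION_WELL_RATIO = 280000.0 / 4314.0


def make_redock_potentials(types, seed: int, n_per_pair: int = 20000,
                           mu: float = 3.6, sigma: float = 0.2):
    """Repulsion-augmented contact potentials for the redocking fixtures.

    Derives from a mini knowledge base in which every pair follows one
    contact law (Gaussian peak at ``mu`` over a uniform floor), against a
    uniform reference, then grafts Gaussian repulsion with a height matched
    to the derived well depth via the published height/depth ratio.
    """
    from .potentials import RepulsionParams, add_repulsion, count_pair_distances, derive_potentials

    kb = make_knowledge_base(contact_laws(types, mu=mu, sigma=sigma),
                             n_per_pair=n_per_pair, seed=seed)
    hists = count_pair_distances(kb, bin_width=0.1, types=types)
    derived = derive_potentials(hists, reference="uniform")
    depth = float(-derived.values.min())
    params = RepulsionParams(height=max(depth, 1e-6) * REPULSION_WELL_RATIO)
    return add_repulsion(derived, params)
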