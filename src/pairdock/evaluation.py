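"""Quality assessment of predicted complexes and docking-success prediction.

Implements the CAPRI-style machinery: interface and contact definitions,
f_nat / f_not / i_rmsd / l_rmsd and the four quality classes; decoy-set
summary percentages with binomial random-selection baselines; Spearman
funnel statistics; bound-vs-unbound difficulty classes; and the relative
solvent-accessible-surface-area (A_rel) predictor of unbound docking
success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import binom, spearmanr

from .errors import CorrespondenceError, ValidationError
from .structure import (
    BACKBONE_ATOMS,
    TypedStructure,
    VDW_RADII,
    apply_pose,
    molecular_weight,
    superposition_onto,
)

INTERFACE_CUTOFF = 10.0  # A: residue is interfacial if any atom within this
CONTACT_CUTOFF = 5.0  # A: residue-residue contact definition

QUALITY_ORDER = ("high", "medium", "acceptable", "incorrect")


# ---------------------------------------------------------------------------
# interface / contact bookkeeping


def _residue_key(s: TypedStructure, i: int) -> tuple:
    return (str(s.chain[i]), int(s.residue_number[i]), str(s.insertion_code[i]))


def _cross_pairs(receptor: TypedStructure, ligand: TypedStructure, cutoff: float):
    """Indices of inter-partner atom pairs with distance < cutoff."""
    neigh = cKDTree(receptor.coords).query_ball_tree(cKDTree(ligand.coords), cutoff)
    for ir, hits in enumerate(neigh):
        if not hits:
            continue
        d = np.linalg.norm(ligand.coords[hits] - receptor.coords[ir], axis=1)
        for il, di in zip(hits, d):
            if di < cutoff:
                yield ir, il


def interface_residues(receptor: TypedStructure, ligand: TypedStructure,
                       cutoff: float = INTERFACE_CUTOFF) -> tuple[set, set]:
    """Residues of each partner with any heavy atom within cutoff of the other."""
    rec_set, lig_set = set(), set()
    for ir, il in _cross_pairs(receptor, ligand, cutoff):
        rec_set.add(_residue_key(receptor, ir))
        lig_set.add(_residue_key(ligand, il))
    return rec_set, lig_set


def contacts(receptor: TypedStructure, ligand: TypedStructure,
             cutoff: float = CONTACT_CUTOFF) -> set:
    """Residue-pair contacts: any heavy-atom pair within cutoff."""
    out = set()
    for ir, il in _cross_pairs(receptor, ligand, cutoff):
        out.add((_residue_key(receptor, ir), _residue_key(ligand, il)))
    return out


# ---------------------------------------------------------------------------
# CAPRI quality classification


def classify_quality(f_nat: float, l_rmsd: float, i_rmsd: float) -> str:
    """Map (f_nat, l_rmsd, i_rmsd) to a CAPRI quality class.

    The printed criteria double-assign the boundary values f_nat = 0.3 and
    0.5; precedence high > medium > acceptable > incorrect resolves the
    overlap.
    """
    high = f_nat >= 0.5 and (l_rmsd <= 1.0 or i_rmsd <= 1.0)
    medium = ((0.3 <= f_nat <= 0.5) and (l_rmsd <= 5.0 or i_rmsd <= 2.0)) or (
        f_nat > 0.5 and l_rmsd > 1.0 and i_rmsd > 1.0
    )
    acceptable = ((0.1 <= f_nat <= 0.3) and (l_rmsd <= 10.0 or i_rmsd <= 4.0)) or (
        f_nat > 0.3 and l_rmsd > 5.0 and i_rmsd > 2.0
    )
    if high:
        return "high"
    if medium:
        return "medium"
    if acceptable:
        return "acceptable"
    return "incorrect"


@dataclass(frozen=True)
class QualityReport:
    f_nat: float
    f_not: float
    i_rmsd: float
    l_rmsd: float
    quality_class: str
    reference_mode: int = 0

    def __post_init__(self):
        if not (0 <= self.f_nat <= 1 and 0 <= self.f_not <= 1):
            raise ValidationError("contact fractions must lie in [0, 1]")
        if self.i_rmsd < 0 or self.l_rmsd < 0:
            raise ValidationError("rmsd values must be non-negative")


def _match_indices(pred: TypedStructure, ref: TypedStructure,
                   ref_mask: np.ndarray | None = None):
    """Pair atoms by (chain, residue number, icode, atom name)."""
    lookup = {}
    for i in range(len(pred)):
        lookup[(_residue_key(pred, i), str(pred.name[i]))] = i
    pi, ri = [], []
    for j in range(len(ref)):
        if ref_mask is not None and not ref_mask[j]:
            continue
        key = (_residue_key(ref, j), str(ref.name[j]))
        if key not in lookup:
            raise CorrespondenceError(f"prediction lacks reference atom {key}")
        pi.append(lookup[key])
        ri.append(j)
    return np.array(pi, dtype=int), np.array(ri, dtype=int)


def _interface_backbone_mask(s: TypedStructure, residues: set) -> np.ndarray:
    return np.array([
        _residue_key(s, i) in residues and str(s.name[i]) in BACKBONE_ATOMS
        for i in range(len(s))
    ])


def _quality_vs_reference(pred_receptor, pred_ligand, ref_receptor, ref_ligand):
    ref_contacts = contacts(ref_receptor, ref_ligand)
    pred_contacts = contacts(pred_receptor, pred_ligand)
    f_nat = (len(ref_contacts & pred_contacts) / len(ref_contacts)) if ref_contacts else 0.0
    f_not = (len(pred_contacts - ref_contacts) / len(pred_contacts)) if pred_contacts else 0.0

    # l_rmsd: superpose receptors on all backbone atoms, measure the ligand
    # backbone without refitting (CAPRI convention)
    pr_i, rr_i = _match_indices(pred_receptor, ref_receptor,
                                np.isin(ref_receptor.name, BACKBONE_ATOMS))
    fit = superposition_onto(ref_receptor.select(rr_i), pred_receptor.select(pr_i))
    pl_i, rl_i = _match_indices(pred_ligand, ref_ligand,
                                np.isin(ref_ligand.name, BACKBONE_ATOMS))
    moved = fit.apply(pred_ligand.coords[pl_i])
    diff = moved - ref_ligand.coords[rl_i]
    l_rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))

    # i_rmsd: backbone of reference-interface residues, least-squares fit on
    # those same residues
    rec_if, lig_if = interface_residues(ref_receptor, ref_ligand)
    pr2, rr2 = _match_indices(pred_receptor, ref_receptor,
                              _interface_backbone_mask(ref_receptor, rec_if))
    pl2, rl2 = _match_indices(pred_ligand, ref_ligand,
                              _interface_backbone_mask(ref_ligand, lig_if))
    ref_coords = np.vstack([ref_receptor.coords[rr2], ref_ligand.coords[rl2]])
    pred_coords = np.vstack([pred_receptor.coords[pr2], pred_ligand.coords[pl2]])
    i_rmsd = _fit_rmsd(ref_coords, pred_coords)
    return QualityReport(f_nat, f_not, i_rmsd, l_rmsd,
                         classify_quality(f_nat, l_rmsd, i_rmsd))


def _fit_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.transform import Rotation
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a - ca, b - cb)
    return float(rssd / np.sqrt(len(a)))


def assess_quality(prediction: tuple[TypedStructure, TypedStructure],
                   references) -> QualityReport:
    """CAPRI-style quality of a predicted complex versus reference mode(s).

    ``references`` is one (receptor, ligand) pair or a sequence of pairs
    (multiple crystallographic binding modes); the best class wins, ties are
    broken by the lowest i_rmsd, and the matched mode index is reported.
    """
    pred_receptor, pred_ligand = prediction
    if isinstance(references, tuple) and isinstance(references[0], TypedStructure):
        references = [references]
    reports = []
    for mode, (ref_r, ref_l) in enumerate(references):
        rep = _quality_vs_reference(pred_receptor, pred_ligand, ref_r, ref_l)
        reports.append(QualityReport(rep.f_nat, rep.f_not, rep.i_rmsd, rep.l_rmsd,
                                     rep.quality_class, reference_mode=mode))
    return min(reports, key=lambda r: (QUALITY_ORDER.index(r.quality_class), r.i_rmsd))


def classify_difficulty(bound: tuple[TypedStructure, TypedStructure],
                        unbound: tuple[TypedStructure, TypedStructure]) -> str:
    """Conformational-change difficulty class: easy / medium / difficult.

    Each unbound partner is superposed onto its bound form (all backbone
    atoms); the assembled pseudo-complex is compared to the bound complex via
    the C-alpha interface rmsd and the fraction of non-native contacts.
    """
    b_rec, b_lig = bound
    u_rec, u_lig = unbound
    placed = []
    for b, u in ((b_rec, u_rec), (b_lig, u_lig)):
        ui, bi = _match_indices(u, b, np.isin(b.name, BACKBONE_ATOMS))
        fit = superposition_onto(b.select(bi), u.select(ui))
        placed.append(apply_pose(u, fit))
    p_rec, p_lig = placed

    rec_if, lig_if = interface_residues(b_rec, b_lig)
    ca_rmsds = []
    for b, pl, resset in ((b_rec, p_rec, rec_if), (b_lig, p_lig, lig_if)):
        mask = np.array([
            _residue_key(b, i) in resset and str(b.name[i]) == "CA"
            for i in range(len(b))
        ])
        pi, bi = _match_indices(pl, b, mask)
        ca_rmsds.append((pl.coords[pi], b.coords[bi]))
    a = np.vstack([x for x, _ in ca_rmsds])
    bb = np.vstack([y for _, y in ca_rmsds])
    ca_irmsd = _fit_rmsd(bb, a)

    bound_contacts = contacts(b_rec, b_lig)
    pseudo_contacts = contacts(p_rec, p_lig)
    f_not = (len(pseudo_contacts - bound_contacts) / len(pseudo_contacts)) if pseudo_contacts else 0.0

    if ca_irmsd > 2.2:
        return "difficult"
    if ca_irmsd >= 1.5 or f_not > 0.4:
        return "medium"
    return "easy"


# ---------------------------------------------------------------------------
# decoy-set statistics and random baselines


@dataclass(frozen=True)
class DecoySetStats:
    """Percentages over targets: R5/R10 (top 10), N10 and best-rmsd (top 5)."""

    r5: float
    r10: float
    n10: float
    best_rmsd: float
    n_targets: int


def decoy_set_metrics(ranked_rmsds: Sequence[Sequence[float]],
                      top_k_cluster: int = 10,
                      top_k_perturbation: int = 5) -> DecoySetStats:
    """Summary percentages over targets, each a ranked list of decoy rmsds.

    R5/R10: at least one of the first ``top_k_cluster`` entries below
    5 A / 10 A.  N10: at least three of the first ``top_k_perturbation``
    below 10 A; best-rmsd: at least one of those below 10 A.
    """
    n = len(ranked_rmsds)
    if n == 0:
        return DecoySetStats(0.0, 0.0, 0.0, 0.0, 0)
    r5 = r10 = n10 = best = 0
    for rmsds in ranked_rmsds:
        arr = np.asarray(rmsds, dtype=float)
        top10 = arr[:top_k_cluster]
        top5 = arr[:top_k_perturbation]
        r5 += bool((top10 < 5.0).any())
        r10 += bool((top10 < 10.0).any())
        n10 += bool((top5 < 10.0).sum() >= 3)
        best += bool((top5 < 10.0).any())
    pct = lambda k: 100.0 * k / n
    return DecoySetStats(pct(r5), pct(r10), pct(n10), pct(best), n)


@dataclass(frozen=True)
class BaselineResult:
    probability: float
    percent: int


def random_baseline(p: float, n_top: int, k_min: int) -> BaselineResult:
    """P(at least k_min acceptable decoys among n_top random picks).

    Binomial tail with per-pick success probability ``p`` (the acceptable
    fraction of the decoy pool); the percent field carries the integer
    rounding used in print.
    """
    if not 0 <= p <= 1:
        raise ValidationError("acceptable fraction must lie in [0, 1]")
    if not 1 <= k_min <= n_top:
        raise ValidationError("need 1 <= k_min <= n_top")
    prob = float(binom.sf(k_min - 1, n_top, p))
    return BaselineResult(prob, int(round(100 * prob)))


# ---------------------------------------------------------------------------
# funnel statistics


@dataclass(frozen=True)
class FunnelStats:
    spearman_rs: float
    n: int


def funnel_spearman(scores: Sequence[float], rmsds: Sequence[float]) -> FunnelStats:
    """Rank correlation between scores and rmsds (average-rank ties).

    Positive values mean better (lower) scores coincide with lower rmsd —
    the signature of a funnel-shaped landscape.
    """
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if len(scores) != len(rmsds) or len(scores) < 3:
        raise ValidationError("need equal-length lists with at least 3 points")
    if np.all(scores == scores[0]) or np.all(rmsds == rmsds[0]):
        raise ValidationError("rank correlation undefined for constant input")
    rs = spearmanr(scores, rmsds).statistic
    return FunnelStats(float(rs), len(scores))


# ---------------------------------------------------------------------------
# solvent-accessible surface area and the A_rel success predictor

# Expected SASA of a folded protein of mass M (Da): c * M^e, a Miller-type
# power law.  The constants ship as configuration; the 1.1 A_rel threshold is
# calibrated against them.
EXPECTED_SASA_COEFF = 6.3
EXPECTED_SASA_EXPONENT = 0.73
AREL_THRESHOLD = 1.1


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def sasa(s: TypedStructure, probe: float = 1.4, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Each atom's sphere of radius (vdW + probe) is sampled at ``n_points``
    near-uniform points; points unoccluded by any neighboring sphere count
    toward the accessible area.
    """
    if len(s) == 0:
        raise ValidationError("sasa of an empty structure")
    radii = np.empty(len(s))
    for i, el in enumerate(s.element):
        try:
            radii[i] = VDW_RADII[str(el).upper()]
        except KeyError:
            raise ValidationError(f"no vdW radius for element {el!r}") from None
    radii = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(s.coords)
    max_r = radii.max()
    total = 0.0
    for i in range(len(s)):
        pts = s.coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(s.coords[i], radii[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - s.coords[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    return float(total)


def expected_sasa(mass_da: float, coeff: float = EXPECTED_SASA_COEFF,
                  exponent: float = EXPECTED_SASA_EXPONENT) -> float:
    if mass_da <= 0:
        raise ValidationError("molecular weight must be positive")
    return float(coeff * mass_da ** exponent)


@dataclass(frozen=True)
class ArelReport:
    sasa: float
    expected_sasa: float
    a_rel: float

    def __post_init__(self):
        if self.sasa <= 0 or self.a_rel <= 0:
            raise ValidationError("sasa and a_rel must be positive")


def a_rel(s: TypedStructure, probe: float = 1.4, n_points: int = 960,
          coeff: float = EXPECTED_SASA_COEFF,
          exponent: float = EXPECTED_SASA_EXPONENT) -> ArelReport:
    """Relative solvent accessibility: actual SASA over the folded-protein
    expectation for the same molecular weight.  Values above ~1.1 flag
    extended, flexible chains likely to change conformation on binding."""
    area = sasa(s, probe=probe, n_points=n_points)
    expect = expected_sasa(molecular_weight(s), coeff, exponent)
    return ArelReport(area, expect, area / expect)


@dataclass(frozen=True)
class SuccessPrediction:
    prediction: str  # "success" | "failure"
    receptor: ArelReport
    ligand: ArelReport


def predict_success(receptor_unbound: TypedStructure,
                    ligand_unbound: TypedStructure,
                    threshold: float = AREL_THRESHOLD,
                    probe: float = 1.4, n_points: int = 960) -> SuccessPrediction:
    """Predict unbound-docking success: both partners need A_rel < threshold
    (strict inequality; A_rel exactly at the threshold predicts failure)."""
    rec = a_rel(receptor_unbound, probe=probe, n_points=n_points)
    lig = a_rel(ligand_unbound, probe=probe, n_points=n_points)
    ok = rec.a_rel < threshold and lig.a_rel < threshold
    return SuccessPrediction("success" if ok else "failure", rec, lig)


def classifier_metrics(predictions: Sequence[bool], outcomes: Sequence[bool]):
    """Sensitivity, specificity, accuracy with success as the positive class."""
    predictions = [bool(x) for x in predictions]
    outcomes = [bool(x) for x in outcomes]
    if not predictions or len(predictions) != len(outcomes):
        raise ValidationError("need equal-length non-empty prediction/outcome lists")
    tp = sum(p and o for p, o in zip(predictions, outcomes))
    tn = sum((not p) and (not o) for p, o in zip(predictions, outcomes))
    fp = sum(p and (not o) for p, o in zip(predictions, outcomes))
    fn = sum((not p) and o for p, o in zip(predictions, outcomes))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(predictions)
    return sens, spec, acc
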