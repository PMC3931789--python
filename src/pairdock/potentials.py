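"""Derivation, augmentation and storage of the distance-dependent pair
potentials.

The potential for an ordered type pair (a, b) at binned distance d is the
inverse-Boltzmann log-ratio

    dW(a, b, d) = -ln( g_ab(d) / g_ref(d) )

where g_ab is the pair's normalized inter-partner distance density over
[0, 5) A and g_ref is a reference density.  Two reference strategies ship:

* ``"type-averaged"`` (default): the distance density pooled over all type
  pairs — the classic knowledge-based convention;
* ``"uniform"``: a flat density over the bins, useful when every pair is
  expected to share one contact law.

Each potential is shifted so its value in the final bin (at the 5 A cutoff)
is zero, and a Gaussian repulsion can be grafted below the first interior
maximum to penalize the short-range region where the knowledge base holds no
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import PotentialFormatError, ValidationError
from .structure import DEFAULT_ALPHABET, TypedStructure

MAX_DISTANCE = 5.0  # A; the derivation and scoring cutoff
SIGNIFICANCE_THRESHOLD = 500  # interactions per pair for a significant potential


@dataclass
class DistanceHistogram:
    """Inter-partner distance counts for one unordered type pair."""

    type_pair: tuple[str, str]
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValidationError("counts/bin_edges length mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RepulsionParams:
    """Gaussian short-range repulsion: height*exp(-d^2/(2 sigma^2)).

    The height at d=0 and the onset offset (added to the first-maximum
    location) are fixed by the method; sigma is configuration — the default
    0.8 A lets the term decay below 0.1% of its height by ~3 A.
    """

    height: float = 280000.0
    width: float = 0.8
    onset_offset: float = 0.1

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("repulsion height and width must be positive")


class PairPotentialSet:
    """Binned dW values, per-pair interaction counts and significance flags.

    ``values`` has shape (T, T, B), symmetric in the first two axes; lookups
    are piecewise-constant on the containing bin (linear interpolation on bin
    centers is available as an option).
    """

    def __init__(self, types: Sequence[str], bin_edges, values, counts,
                 repulsion_applied: bool = False):
        self.types = tuple(types)
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.repulsion_applied = bool(repulsion_applied)
        t, b = len(self.types), len(self.bin_edges) - 1
        if self.values.shape != (t, t, b) or self.counts.shape != (t, t):
            raise ValidationError("potential array shapes inconsistent with types/bins")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("potential values must be finite")
        self._index = {typ: i for i, typ in enumerate(self.types)}

    # -- lookups -----------------------------------------------------------

    def type_index(self, typ: str) -> int:
        try:
            return self._index[typ]
        except KeyError:
            raise ValidationError(f"atom type {typ!r} not in potential alphabet") from None

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def pair_values(self, type_a: str, type_b: str) -> np.ndarray:
        return self.values[self.type_index(type_a), self.type_index(type_b)]

    def pair_count(self, type_a: str, type_b: str) -> int:
        return int(self.counts[self.type_index(type_a), self.type_index(type_b)])

    def value_at(self, type_a: str, type_b: str, distance, interpolate: bool = False):
        """dW at the given distance(s); zero at or beyond the 5 A cutoff."""
        vals = self.pair_values(type_a, type_b)
        d = np.asarray(distance, dtype=float)
        if interpolate:
            out = np.interp(d, self.bin_centers, vals)
        else:
            idx = np.clip((d / self.bin_width).astype(int), 0, len(vals) - 1)
            out = vals[idx]
        out = np.where(d >= self.bin_edges[-1], 0.0, out)
        return float(out) if np.isscalar(distance) else out

    def significance_flags(self) -> np.ndarray:
        return self.counts >= SIGNIFICANCE_THRESHOLD

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PairPotentialSet)
            and self.types == other.types
            and np.array_equal(self.bin_edges, other.bin_edges)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.counts, other.counts)
            and self.repulsion_applied == other.repulsion_applied
        )


# ---------------------------------------------------------------------------
# counting


def count_pair_distances(
    complexes: Iterable[tuple[TypedStructure, TypedStructure]],
    bin_width: float = 0.1,
    types: Sequence[str] = DEFAULT_ALPHABET,
) -> list[DistanceHistogram]:
    """Histogram inter-partner atom-pair distances below 5 A.

    Only cross-partner pairs are counted; (a, b) and (b, a) observations are
    accumulated into one symmetric histogram per unordered type pair.  All
    unordered pairs of the alphabet are returned, including zero-count ones.
    """
    n_bins = round(MAX_DISTANCE / bin_width)
    if not np.isclose(n_bins * bin_width, MAX_DISTANCE):
        raise ValidationError(f"bin width {bin_width} does not divide {MAX_DISTANCE} A evenly")
    edges = np.linspace(0.0, MAX_DISTANCE, n_bins + 1)
    index = {t: i for i, t in enumerate(types)}
    counts = np.zeros((len(types), len(types), n_bins), dtype=np.int64)
    for k, (part_a, part_b) in enumerate(complexes):
        for part in (part_a, part_b):
            if not part.is_typed:
                raise ValidationError(
                    f"untyped atoms in complex #{k} ({part.provenance or 'in-memory'})"
                )
        ta = np.array([index[t] for t in part_a.atom_type])
        tb = np.array([index[t] for t in part_b.atom_type])
        pairs = cKDTree(part_a.coords).query_ball_tree(cKDTree(part_b.coords), MAX_DISTANCE)
        for ia, neigh in enumerate(pairs):
            if not neigh:
                continue
            d = np.linalg.norm(part_b.coords[neigh] - part_a.coords[ia], axis=1)
            inside = d < MAX_DISTANCE
            bins = np.minimum((d[inside] / bin_width).astype(int), n_bins - 1)
            for ib, bi in zip(np.asarray(neigh)[inside], bins):
                counts[ta[ia], tb[ib], bi] += 1
    counts = counts + np.swapaxes(counts, 0, 1)  # symmetrize: (a,b) and (b,a) pooled
    out = []
    for i, a in enumerate(types):
        for j in range(i, len(types)):
            c = counts[i, j] if i != j else counts[i, j] // 2
            out.append(DistanceHistogram((a, types[j]), edges, c))
    return out


# ---------------------------------------------------------------------------
# derivation


def derive_potentials(
    histograms: Iterable[DistanceHistogram],
    reference: str = "type-averaged",
    pseudo_count: float = 1.0,
) -> PairPotentialSet:
    """Turn distance histograms into a zero-anchored pair-potential set.

    A pseudo-count is added to every bin before normalization so that empty
    bins stay finite; each pair's potential is shifted so its final bin
    (at the 5 A cutoff) is exactly zero.
    """
    histograms = list(histograms)
    if not histograms:
        raise ValidationError("no histograms given")
    edges = histograms[0].bin_edges
    types = sorted({t for h in histograms for t in h.type_pair})
    index = {t: i for i, t in enumerate(types)}
    n_bins = len(edges) - 1
    raw = np.zeros((len(types), len(types), n_bins))
    counts = np.zeros((len(types), len(types)), dtype=np.int64)
    for h in histograms:
        if not np.array_equal(h.bin_edges, edges):
            raise ValidationError("histograms do not share bin edges")
        i, j = index[h.type_pair[0]], index[h.type_pair[1]]
        raw[i, j] = raw[j, i] = h.counts
        counts[i, j] = counts[j, i] = h.total
    if raw.sum() == 0:
        raise ValidationError("all histograms are empty; cannot derive potentials")

    smoothed = raw + pseudo_count
    g_pair = smoothed / smoothed.sum(axis=2, keepdims=True)
    if reference == "type-averaged":
        # pool over unordered pairs: upper triangle including the diagonal
        iu = np.triu_indices(len(types))
        pooled = smoothed[iu].sum(axis=0)
        g_ref = pooled / pooled.sum()
    elif reference == "uniform":
        g_ref = np.full(n_bins, 1.0 / n_bins)
    else:
        raise ValidationError(f"unknown reference strategy {reference!r}")
    values = -np.log(g_pair / g_ref)
    values = values - values[:, :, -1:]  # zero anchor at the 5 A bin
    return PairPotentialSet(types, edges, values, counts, repulsion_applied=False)


def first_maximum_bin(values: np.ndarray) -> int:
    """Index of the repulsion-onset bin for one pair potential.

    Scanning from d = 0, the first bin strictly exceeding both neighbors and
    lying before the global minimum; if no such interior maximum exists, fall
    back to the bin just before the global minimum.
    """
    gmin = int(np.argmin(values))
    for i in range(1, gmin):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            return i
    return max(gmin - 1, 0)


def repulsion_term(params: RepulsionParams, distance) -> np.ndarray:
    """The Gaussian repulsion value at a distance: exactly ``height`` at 0 A."""
    d = np.asarray(distance, dtype=float)
    return params.height * np.exp(-(d ** 2) / (2 * params.width ** 2))


def add_repulsion(p: PairPotentialSet, params: RepulsionParams | None = None) -> PairPotentialSet:
    """Graft Gaussian short-range repulsion below each pair's first maximum.

    Bins whose center lies below (first-maximum location + onset offset) gain
    ``height * exp(-d^2 / (2 sigma^2))``; bins at or beyond the onset are
    untouched.  Application is recorded and may not be repeated.
    """
    if params is None:
        params = RepulsionParams()
    if p.repulsion_applied:
        raise ValidationError("repulsion already applied to this potential set")
    centers = p.bin_centers
    values = p.values.copy()
    gauss = repulsion_term(params, centers)
    for i in range(len(p.types)):
        for j in range(i, len(p.types)):
            onset = centers[first_maximum_bin(values[i, j])] + params.onset_offset
            window = centers < onset
            values[i, j, window] += gauss[window]
            values[j, i] = values[i, j]
    return PairPotentialSet(p.types, p.bin_edges, values, p.counts, repulsion_applied=True)


def significance_report(p: PairPotentialSet) -> pd.DataFrame:
    """One row per unordered type pair: interaction count and significance."""
    rows = []
    flags = p.significance_flags()
    for i, a in enumerate(p.types):
        for j in range(i, len(p.types)):
            rows.append({
                "type_a": a,
                "type_b": p.types[j],
                "count": int(p.counts[i, j]),
                "significant": bool(flags[i, j]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence (canonical TSV: type_a <= type_b, ascending bins)


def save_potentials(p: PairPotentialSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#types\t{','.join(p.types)}\n")
        fh.write(f"#repulsion_applied\t{int(p.repulsion_applied)}\n")
        fh.write("type_a\ttype_b\tbin_lo\tbin_hi\tcount\tdelta_w\trepulsion_flag\n")
        for i, a in enumerate(p.types):
            for j in range(i, len(p.types)):
                b = p.types[j]
                for k in range(len(p.bin_edges) - 1):
                    fh.write(
                        f"{a}\t{b}\t{p.bin_edges[k]:.17g}\t{p.bin_edges[k + 1]:.17g}"
                        f"\t{p.counts[i, j]}\t{p.values[i, j, k]:.17g}"
                        f"\t{int(p.repulsion_applied)}\n"
                    )


def load_potentials(path) -> PairPotentialSet:
    types: tuple[str, ...] | None = None
    repulsion = False
    data: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#types\t"):
                types = tuple(line.split("\t")[1].split(","))
                continue
            if line.startswith("#repulsion_applied\t"):
                repulsion = bool(int(line.split("\t")[1]))
                continue
            if line.startswith("type_a\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise PotentialFormatError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                a, b = parts[0], parts[1]
                lo, hi, cnt, val = float(parts[2]), float(parts[3]), int(parts[4]), float(parts[5])
            except ValueError as exc:
                raise PotentialFormatError(f"{path}:{lineno}: {exc}") from exc
            entry = data.setdefault((a, b), {"edges": [], "values": [], "count": cnt})
            entry["edges"].append((lo, hi))
            entry["values"].append(val)
    if types is None:
        raise PotentialFormatError(f"{path}: missing #types header")
    some = next(iter(data.values()), None)
    if some is None:
        raise PotentialFormatError(f"{path}: no data rows")
    n_bins = len(some["edges"])
    edges = np.array([lo for lo, _ in some["edges"]] + [some["edges"][-1][1]])
    values = np.zeros((len(types), len(types), n_bins))
    counts = np.zeros((len(types), len(types)), dtype=np.int64)
    index = {t: i for i, t in enumerate(types)}
    for i, a in enumerate(types):
        for j in range(i, len(types)):
            b = types[j]
            if (a, b) not in data:
                raise PotentialFormatError(f"{path}: missing pair {a}-{b}")
            entry = data[(a, b)]
            if len(entry["values"]) != n_bins:
                raise PotentialFormatError(f"{path}: pair {a}-{b} has {len(entry['values'])} bins, expected {n_bins}")
            values[i, j] = values[j, i] = entry["values"]
            counts[i, j] = counts[j, i] = entry["count"]
    return PairPotentialSet(types, edges, values, counts, repulsion_applied=repulsion)
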