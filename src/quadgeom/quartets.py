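"""G-quartet detection, stacked-core assembly, channel ions, fold topology.

A G-quartet is found purely geometrically, as a directed 4-cycle of
Hoogsteen hydrogen bonds between guanines: guanine g donates to h when
dist(N1(g), O6(h)) and dist(N2(g), N7(h)) are both below the hydrogen-bond
cutoff. Sequence order is never used, so a guanine outside any G-tract that
folds back into the core (a snapback guanine) is detected like any other.
The criterion is hydrogen-free (donor-acceptor heavy-atom distances only)
because crystal structures carry no hydrogens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Plane, best_fit_plane
from .structures import Residue, Structure, base_code, is_nucleotide, is_purine

__all__ = [
    "PURINE_RING_ATOMS",
    "PYRIMIDINE_RING_ATOMS",
    "Quartet",
    "QuartetCore",
    "IonAssignment",
    "Loop",
    "TopologyReport",
    "TopologyError",
    "StackingBreakError",
    "ring_atom_names",
    "ring_centroid",
    "detect_quartets",
    "build_core",
    "assign_ions",
    "classify_topology",
]

PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")

# monatomic cations that can occupy the central channel or decorate loops
_CATION_ELEMENTS = {"K", "NA", "MG", "CA", "SR", "BA", "LI", "RB", "CS", "TL", "MN", "ZN"}


class TopologyError(ValueError):
    """The chain/core combination does not describe a recognizable fold."""


class StackingBreakError(ValueError):
    """Quartets do not form a contiguous stack."""


def ring_atom_names(residue: Residue) -> tuple[str, ...]:
    return PURINE_RING_ATOMS if is_purine(residue.name) else PYRIMIDINE_RING_ATOMS


def ring_coords(residue: Residue) -> np.ndarray:
    """Positions of the base ring atoms present on a residue."""
    pts = [a.position for a in residue.atoms if a.name in ring_atom_names(residue)]
    return np.array(pts, dtype=float)


def ring_centroid(residue: Residue) -> np.ndarray:
    pts = ring_coords(residue)
    if len(pts) < 3:
        raise TopologyError(f"residue {residue.label}: fewer than 3 ring atoms")
    return pts.mean(axis=0)


@dataclass(frozen=True)
class Quartet:
    """Four guanines in Hoogsteen donor->acceptor cyclic order."""

    guanines: tuple[Residue, Residue, Residue, Residue]
    plane: Plane
    planarity_rms: float

    @property
    def hbond_order(self) -> tuple[tuple[str, int], ...]:
        return tuple(g.key for g in self.guanines)

    @property
    def centroid(self) -> np.ndarray:
        return self.plane.centroid

    def member_keys(self) -> frozenset:
        return frozenset(g.key for g in self.guanines)


@dataclass
class QuartetCore:
    """Ordered quartet stack: the geometric reference frame for all calls.

    ``layers[0]`` is the quartet containing the 5'-most core guanine (the
    "bottom" face); ``axis`` points from that layer toward the other end, so
    "up" is reproducible across files.
    """

    layers: list[Quartet]
    axis: np.ndarray
    rise_per_layer: list[float]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_centroids(self) -> np.ndarray:
        return np.array([q.centroid for q in self.layers])

    def layer_of(self) -> dict[tuple[str, int], int]:
        return {g.key: i for i, q in enumerate(self.layers) for g in q.guanines}

    def core_keys(self) -> set[tuple[str, int]]:
        return {g.key for q in self.layers for g in q.guanines}

    def axial_radial(self, point) -> tuple[float, float, int]:
        """Signed axial and radial components of a point relative to the
        nearest layer centroid; returns (axial, radial, layer index)."""
        point = np.asarray(point, dtype=float)
        cents = self.layer_centroids
        nearest = int(np.argmin(np.linalg.norm(cents - point, axis=1)))
        v = point - cents[nearest]
        axial = float(v @ self.axis)
        radial = float(np.linalg.norm(v - axial * self.axis))
        return axial, radial, nearest


@dataclass
class IonAssignment:
    channel_ions: list[tuple[Residue, int]] = field(default_factory=list)
    external_ions: list[tuple[Residue, str]] = field(default_factory=list)


@dataclass(frozen=True)
class Loop:
    residues: tuple[Residue, ...]
    loop_type: str  # propeller | lateral | diagonal

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.residues)


@dataclass
class TopologyReport:
    tracts: list[tuple[int, int]]
    loops: list[Loop]
    strand_senses: list[str]
    snapback_residues: list[Residue]
    n_layers: int
    columns: list[list[Residue]] = field(default_factory=list)

    @property
    def snapback_labels(self) -> list[str]:
        return [r.label for r in self.snapback_residues]


# ---------------------------------------------------------------------------
# quartet detection


def _hoogsteen_edges(guanines: list[Residue], hbond_max: float) -> np.ndarray:
    n = len(guanines)
    n1 = np.array([g.atom("N1").position for g in guanines])
    n2 = np.array([g.atom("N2").position for g in guanines])
    o6 = np.array([g.atom("O6").position for g in guanines])
    n7 = np.array([g.atom("N7").position for g in guanines])
    d_n1_o6 = np.linalg.norm(n1[:, None, :] - o6[None, :, :], axis=2)
    d_n2_n7 = np.linalg.norm(n2[:, None, :] - n7[None, :, :], axis=2)
    adj = (d_n1_o6 <= hbond_max) & (d_n2_n7 <= hbond_max)
    np.fill_diagonal(adj, False)
    return adj


def _four_cycles(adj: np.ndarray) -> list[tuple[int, int, int, int]]:
    """All directed 4-cycles over distinct nodes, one representative each."""
    n = adj.shape[0]
    seen: set[frozenset] = set()
    cycles = []
    for a in range(n):
        for b in np.flatnonzero(adj[a]):
            if b == a:
                continue
            for c in np.flatnonzero(adj[b]):
                if c in (a, b):
                    continue
                for d in np.flatnonzero(adj[c]):
                    if d in (a, b, c) or not adj[d, a]:
                        continue
                    key = frozenset((a, int(b), int(c), int(d)))
                    if key not in seen:
                        seen.add(key)
                        cycles.append((a, int(b), int(c), int(d)))
    return cycles


def _canonical_cycle(cycle, guanines) -> tuple[Residue, ...]:
    """Rotate the donor->acceptor cycle so the 5'-most guanine comes first."""
    keys = [guanines[i].key for i in cycle]
    start = keys.index(min(keys))
    order = cycle[start:] + cycle[:start]
    return tuple(guanines[i] for i in order)


def detect_quartets(
    structure: Structure,
    hbond_max: float = 3.5,
    planarity_max: float = 1.0,
) -> list[Quartet]:
    """Geometric G-quartet detection.

    Candidate quartets are directed Hoogsteen 4-cycles whose pooled base
    ring atoms fit a plane with RMS deviation <= ``planarity_max``; each
    guanine joins at most one quartet (greedy, most planar first).
    Guanines missing any of N1/N2/O6/N7 are skipped with a warning.
    """
    guanines = []
    for res in structure.residues():
        if base_code(res.name) != "G":
            continue
        if all(res.atom(n) is not None for n in ("N1", "N2", "O6", "N7")):
            guanines.append(res)
        else:
            warnings.warn(
                f"guanine {res.chain_id}/{res.label} lacks Hoogsteen atoms; skipped",
                stacklevel=2,
            )
    if len(guanines) < 4:
        return []
    adj = _hoogsteen_edges(guanines, hbond_max)
    candidates = []
    for cycle in _four_cycles(adj):
        members = _canonical_cycle(cycle, guanines)
        pts = np.vstack([ring_coords(g) for g in members])
        plane = best_fit_plane(pts)
        rms = float(np.sqrt(np.mean(plane.signed_distance(pts) ** 2)))
        if rms <= planarity_max:
            candidates.append(Quartet(guanines=members, plane=plane, planarity_rms=rms))
    # greedy disambiguation: best (most planar) first, deterministic tie-break
    candidates.sort(key=lambda q: (q.planarity_rms, q.hbond_order))
    used: set = set()
    selected = []
    for q in candidates:
        if used.isdisjoint(q.member_keys()):
            selected.append(q)
            used |= q.member_keys()
    return selected


# ---------------------------------------------------------------------------
# core assembly


def build_core(
    quartets: list[Quartet],
    stack_window: tuple[float, float] = (2.8, 4.5),
) -> QuartetCore:
    """Order quartets along their common axis into a stacked core.

    Consecutive layer-centroid separations must fall inside
    ``stack_window`` (Angstrom), otherwise :class:`StackingBreakError`
    names the offending gap. Input order is irrelevant — the stack order is
    recovered from geometry alone.
    """
    if len(quartets) < 2:
        raise ValueError("a core needs at least 2 quartets")
    centroids = np.array([q.centroid for q in quartets])
    centered = centroids - centroids.mean(axis=0)
    # stacking direction: principal axis of the centroid cloud
    _, _, vt = np.linalg.svd(centered)
    direction = vt[0]
    order = np.argsort(centered @ direction)
    layers = [quartets[i] for i in order]
    rises = [
        float(np.linalg.norm(layers[i + 1].centroid - layers[i].centroid))
        for i in range(len(layers) - 1)
    ]
    for i, r in enumerate(rises):
        if not (stack_window[0] <= r <= stack_window[1]):
            a = ",".join(g.label for g in layers[i].guanines)
            b = ",".join(g.label for g in layers[i + 1].guanines)
            raise StackingBreakError(
                f"layers ({a}) and ({b}) are {r:.2f} A apart; "
                f"outside stacking window {stack_window}"
            )
    # anchor: the layer holding the 5'-most core guanine becomes layers[0]
    five_prime = min(g.key for q in layers for g in q.guanines)
    holder = next(i for i, q in enumerate(layers) if five_prime in {g.key for g in q.guanines})
    if holder > len(layers) - 1 - holder:
        layers = layers[::-1]
        rises = rises[::-1]
    axis = layers[-1].centroid - layers[0].centroid
    axis = axis / np.linalg.norm(axis)
    return QuartetCore(layers=layers, axis=axis, rise_per_layer=rises)


# ---------------------------------------------------------------------------
# ions


def _is_monatomic_cation(res: Residue) -> bool:
    return len(res.atoms) == 1 and res.atoms[0].element.upper() in _CATION_ELEMENTS


def assign_ions(
    core: QuartetCore,
    structure: Structure,
    radial_max: float = 2.5,
) -> IonAssignment:
    """Split monatomic cations into channel ions and external ions.

    A channel ion projects axially between the first and last layer
    centroid (with half-a-rise slack at either face) and lies within
    ``radial_max`` of the axis; each one carries the index of the
    inter-layer gap it occupies (-1 = below the bottom face).
    """
    result = IonAssignment()
    cents = core.layer_centroids
    ts = cents @ core.axis
    mean_rise = float(np.mean(core.rise_per_layer))
    lo, hi = ts[0] - mean_rise / 2, ts[-1] + mean_rise / 2
    origin = cents[0]
    for res in structure.residues():
        if not _is_monatomic_cation(res):
            continue
        pos = res.atoms[0].position
        t = float(pos @ core.axis)
        v = pos - origin
        radial = float(np.linalg.norm(v - (v @ core.axis) * core.axis))
        if lo <= t <= hi and radial <= radial_max:
            gap = int(np.clip(np.searchsorted(ts, t) - 1, -1, core.n_layers - 1))
            result.channel_ions.append((res, gap))
        else:
            nearest, best = "", np.inf
            for other in structure.residues():
                if other is res or _is_monatomic_cation(other):
                    continue
                d = float(np.min(np.linalg.norm(other.coords() - pos, axis=1)))
                if d < best:
                    best, nearest = d, f"{other.chain_id}/{other.label}"
            result.external_ions.append((res, nearest))
    return result


# ---------------------------------------------------------------------------
# topology


def _assign_columns(core: QuartetCore) -> list[list[Residue]]:
    """Group quartet members into vertical columns across layers.

    Columns are seeded by the cyclic order of the bottom quartet; members of
    each subsequent layer are matched to columns by lateral (axis-
    perpendicular) distance via optimal assignment.
    """
    axis = core.axis

    def lateral(p):
        return p - (p @ axis) * axis

    columns = [[g] for g in core.layers[0].guanines]
    for quartet in core.layers[1:]:
        tops = [lateral(ring_centroid(col[-1])) for col in columns]
        cands = list(quartet.guanines)
        cand_pts = [lateral(ring_centroid(g)) for g in cands]
        cost = np.array([[np.linalg.norm(t - c) for c in cand_pts] for t in tops])
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            columns[r].append(cands[c])
    return columns


def _runs(sorted_seqs: list[int]) -> list[list[int]]:
    runs, current = [], [sorted_seqs[0]]
    for s in sorted_seqs[1:]:
        if s == current[-1] + 1:
            current.append(s)
        else:
            runs.append(current)
            current = [s]
    runs.append(current)
    return runs


def classify_topology(core: QuartetCore, chain: Structure) -> TopologyReport:
    """Tracts, loop types, strand senses and snapback residues of one chain.

    Strand sense per column is the sign of the backbone C1' progression
    along the core axis versus sequence order, reported relative to the
    first column. Loops are typed from the faces and corners they join:
    opposite faces -> propeller (groove-traversing, double-chain reversal);
    same face, adjacent corners -> lateral; same face, opposite corners ->
    diagonal.
    """
    chain_ids = list(chain.chains)
    if len(chain_ids) != 1:
        raise TopologyError(f"classify_topology expects a single chain, got {chain_ids}")
    nts = chain.nucleotides(chain_ids[0])
    chain_keys = {r.key for r in nts}
    core_keys = core.core_keys()
    if not core_keys <= chain_keys:
        missing = sorted(core_keys - chain_keys)
        raise TopologyError(f"chain lacks core guanines {missing}")

    columns = _assign_columns(core)
    column_of = {g.key: j for j, col in enumerate(columns) for g in col}
    layer_of = core.layer_of()
    by_key = {r.key: r for r in nts}
    n_layers = core.n_layers

    # tracts and snapbacks: consecutive-sequence runs within each column
    tracts: list[tuple[int, int]] = []
    snapback: list[Residue] = []
    for col in columns:
        seqs = sorted(g.seq_number for g in col)
        for run in _runs(seqs):
            tracts.append((run[0], run[-1]))
            if len(run) == 1:
                snapback.append(by_key[(col[0].chain_id, run[0])])
    tracts.sort()

    # strand sense: slope of axial C1' coordinate vs sequence order
    senses_sign = []
    for col in columns:
        ordered = sorted(col, key=lambda g: g.seq_number)
        heights = []
        for g in ordered:
            anchor = g.atom("C1'")
            pos = anchor.position if anchor is not None else ring_centroid(g)
            heights.append(float(pos @ core.axis))
        slope = np.polyfit(range(len(ordered)), heights, 1)[0]
        senses_sign.append(np.sign(slope) or 1.0)
    strand_senses = [
        "parallel" if s == senses_sign[0] else "antiparallel" for s in senses_sign
    ]

    # loops: maximal non-core nucleotide runs strictly between core residues
    def face(layer: int) -> int:
        return 0 if layer <= (n_layers - 1) / 2 else 1

    loops: list[Loop] = []
    i = 0
    while i < len(nts):
        if nts[i].key in core_keys:
            i += 1
            continue
        j = i
        while j < len(nts) and nts[j].key not in core_keys:
            j += 1
        before = nts[i - 1] if i > 0 else None
        after = nts[j] if j < len(nts) else None
        if before is not None and after is not None:
            lb, la = layer_of[before.key], layer_of[after.key]
            cb, ca = column_of[before.key], column_of[after.key]
            if face(lb) != face(la):
                ltype = "propeller"
            elif abs(cb - ca) % 4 == 2:
                ltype = "diagonal"
            else:
                ltype = "lateral"
            loops.append(Loop(residues=tuple(nts[i:j]), loop_type=ltype))
        i = j

    return TopologyReport(
        tracts=tracts,
        loops=loops,
        strand_senses=strand_senses,
        snapback_residues=snapback,
        n_layers=n_layers,
        columns=columns,
    )
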