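"""Synthetic structure generators with exact ground truth.

Three generators drive the test suite and the acceptance checks:

* an idealized intramolecular quadruplex built from standard nucleotide
  geometry (biotite's bundled chemical-component dictionary), with known
  layer count, helical twist and rise, planted loop-base orientations and
  channel cations — plus an idealized B-DNA-like duplex as negative control;
* an internal-coordinate chain builder (natural-extension / NeRF) whose
  prescribed backbone and glycosidic torsions are recovered exactly by the
  torsion module, serving as its round-trip oracle;
* Gaussian perturbation ensembles with a prescribed per-residue fluctuation
  profile, and multi-trajectory frame sets with planted cluster centers and
  a planted transition schedule.

The loop backbone of the synthetic quadruplex is geometrically plausible
but not energy-minimized: sufficient for the geometric classifiers, not for
force-field work.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .quartets import PURINE_RING_ATOMS, PYRIMIDINE_RING_ATOMS
from .structures import Atom, Ensemble, Residue, Structure, is_purine

__all__ = [
    "ConstructionError",
    "ICEntry",
    "InternalCoordinateTable",
    "backbone_ic_table",
    "build_chain",
    "QuadruplexSpec",
    "build_quadruplex",
    "build_bdna_duplex",
    "PerturbationSpec",
    "perturb_ensemble",
    "TrajectorySpec",
    "generate_trajectories",
    "make_cluster_centers",
    "copy_structure",
]


class ConstructionError(ValueError):
    """A generator specification cannot be realized geometrically."""


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) chain building


@dataclass(frozen=True)
class ICEntry:
    """One atom given by bond length/angle/dihedral against three references.

    ``ref_a/ref_b/ref_c`` are indices of previously placed atoms; the new
    atom D bonds to ``ref_c`` with bond length ``length``, angle D-C-B =
    ``angle`` and dihedral D-C-B-A = ``dihedral`` (degrees). The first three
    atoms seed a canonical frame and use -1 for absent references.
    """

    name: str
    res_index: int
    length: float
    angle: float
    dihedral: float
    ref_a: int
    ref_b: int
    ref_c: int


@dataclass
class InternalCoordinateTable:
    entries: list[ICEntry]
    residue_names: list[str]
    chain_id: str = "A"

    def validate(self) -> None:
        for i, e in enumerate(self.entries):
            if i >= 1 and not (0.8 < e.length < 2.0):
                raise ConstructionError(f"entry {i} ({e.name}): bond length {e.length} A")
            if i >= 2 and not (0.0 < e.angle < 180.0):
                raise ConstructionError(f"entry {i} ({e.name}): bond angle {e.angle}")
            for ref in (e.ref_a, e.ref_b, e.ref_c):
                if ref >= i:
                    raise ConstructionError(
                        f"entry {i} ({e.name}): reference {ref} does not precede it"
                    )


def _nerf_place(a, b, c, length: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural-extension placement of D from references A, B, C."""
    theta = np.radians(angle)
    phi = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


def build_chain(ic: InternalCoordinateTable) -> Structure:
    """Cartesian coordinates from an internal-coordinate table.

    The first atom sits at the origin, the second along +x, the third in the
    xy-plane honoring its bond angle; every further atom is placed by
    natural extension so each prescribed dihedral is realized exactly.
    """
    ic.validate()
    coords = np.zeros((len(ic.entries), 3))
    for i, e in enumerate(ic.entries):
        if i == 0:
            coords[i] = (0.0, 0.0, 0.0)
        elif i == 1:
            coords[i] = (e.length, 0.0, 0.0)
        elif i == 2:
            theta = np.radians(e.angle)
            coords[i] = coords[e.ref_c] + e.length * np.array(
                [-np.cos(theta), np.sin(theta), 0.0]
            )
        else:
            coords[i] = _nerf_place(
                coords[e.ref_a], coords[e.ref_b], coords[e.ref_c],
                e.length, e.angle, e.dihedral,
            )
    residues: list[Residue] = []
    for ri, name in enumerate(ic.residue_names):
        atoms = [
            Atom(name=e.name, element=_element_of(e.name), position=coords[i])
            for i, e in enumerate(ic.entries)
            if e.res_index == ri
        ]
        residues.append(
            Residue(chain_id=ic.chain_id, seq_number=ri + 1, name=name, atoms=atoms)
        )
    return Structure(model_id=1, chains={ic.chain_id: residues})


# standard backbone geometry (lengths A, angles degrees)
_BB_LEN = {
    ("P", "O5'"): 1.593, ("O5'", "C5'"): 1.440, ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524, ("C3'", "O3'"): 1.423, ("O3'", "P"): 1.607,
    ("C4'", "O4'"): 1.446, ("O4'", "C1'"): 1.420,
    ("C1'", "N"): 1.468, ("N", "C"): 1.374,
}
_BB_ANG = {
    "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.9, "O5'-C5'-C4'": 111.5,
    "C5'-C4'-C3'": 116.0, "C4'-C3'-O3'": 110.0, "C3'-O3'-P": 119.7,
    "C5'-C4'-O4'": 109.0, "C4'-O4'-C1'": 109.7, "O4'-C1'-N": 108.2,
    "C1'-N-C": 126.0,
}


def backbone_ic_table(torsions: list[dict], names: list[str] | None = None) -> InternalCoordinateTable:
    """Internal-coordinate table for an n-mer chain with prescribed torsions.

    ``torsions[i]`` holds the residue's backbone angles (keys among alpha,
    beta, gamma, delta, epsilon, zeta, chi, degrees). alpha/beta of the
    first residue are ignored (5' terminus without phosphate), epsilon/zeta
    of the last are ignored. Residue names default to DG; pyrimidine names
    get the N1/C2 glycosidic atoms, purines N9/C4.
    """
    n = len(torsions)
    if n < 1:
        raise ConstructionError("need at least one residue")
    if names is None:
        names = ["DG"] * n
    if len(names) != n:
        raise ConstructionError("names must pair 1:1 with torsion dicts")
    entries: list[ICEntry] = []
    index: dict[tuple[int, str], int] = {}

    def add(name, ri, length, angle, dihedral, refs):
        entries.append(ICEntry(name, ri, length, angle, dihedral, *refs))
        index[(ri, name)] = len(entries) - 1

    def at(ri, name) -> int:
        return index[(ri, name)]

    for i, t in enumerate(torsions):
        g = {k: float(v) for k, v in t.items()}
        purine = is_purine(names[i])
        n_gly, c_gly = ("N9", "C4") if purine else ("N1", "C2")
        if i == 0:
            add("O5'", 0, 0.0, 0.0, 0.0, (-1, -1, -1))
            add("C5'", 0, _BB_LEN[("O5'", "C5'")], 0.0, 0.0, (-1, -1, at(0, "O5'")))
            add("C4'", 0, _BB_LEN[("C5'", "C4'")], _BB_ANG["O5'-C5'-C4'"], 0.0,
                (-1, at(0, "O5'"), at(0, "C5'")))
        else:
            prev = i - 1
            tp = {k: float(v) for k, v in torsions[prev].items()}
            add("P", i, _BB_LEN[("O3'", "P")], _BB_ANG["C3'-O3'-P"],
                tp.get("epsilon", 180.0),
                (at(prev, "C4'"), at(prev, "C3'"), at(prev, "O3'")))
            add("O5'", i, _BB_LEN[("P", "O5'")], _BB_ANG["O3'-P-O5'"],
                tp.get("zeta", 180.0),
                (at(prev, "C3'"), at(prev, "O3'"), at(i, "P")))
            add("C5'", i, _BB_LEN[("O5'", "C5'")], _BB_ANG["P-O5'-C5'"],
                g.get("alpha", 180.0),
                (at(prev, "O3'"), at(i, "P"), at(i, "O5'")))
            add("C4'", i, _BB_LEN[("C5'", "C4'")], _BB_ANG["O5'-C5'-C4'"],
                g.get("beta", 180.0),
                (at(i, "P"), at(i, "O5'"), at(i, "C5'")))
        add("C3'", i, _BB_LEN[("C4'", "C3'")], _BB_ANG["C5'-C4'-C3'"],
            g.get("gamma", 180.0),
            (at(i, "O5'"), at(i, "C5'"), at(i, "C4'")))
        add("O3'", i, _BB_LEN[("C3'", "O3'")], _BB_ANG["C4'-C3'-O3'"],
            g.get("delta", 180.0),
            (at(i, "C5'"), at(i, "C4'"), at(i, "C3'")))
        # sugar/base branch: auxiliary dihedrals are fixed, chi is prescribed
        gamma = g.get("gamma", 180.0)
        add("O4'", i, _BB_LEN[("C4'", "O4'")], _BB_ANG["C5'-C4'-O4'"],
            gamma + 121.0, (at(i, "O5'"), at(i, "C5'"), at(i, "C4'")))
        add("C1'", i, _BB_LEN[("O4'", "C1'")], _BB_ANG["C4'-O4'-C1'"],
            -95.0, (at(i, "C5'"), at(i, "C4'"), at(i, "O4'")))
        add(n_gly, i, _BB_LEN[("C1'", "N")], _BB_ANG["O4'-C1'-N"],
            70.0, (at(i, "C4'"), at(i, "O4'"), at(i, "C1'")))
        add(c_gly, i, _BB_LEN[("N", "C")], _BB_ANG["C1'-N-C"],
            g.get("chi", 180.0), (at(i, "O4'"), at(i, "C1'"), at(i, n_gly)))
    return InternalCoordinateTable(entries=entries, residue_names=list(names))


# ---------------------------------------------------------------------------
# nucleotide templates from the chemical-component dictionary


def _rz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _align_z(normal) -> np.ndarray:
    """Rotation mapping +z onto ``normal`` (Rodrigues)."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    c = float(z @ n)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


@lru_cache(maxsize=None)
def nucleotide_template(resname: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Ideal heavy-atom nucleotide geometry in a base-centered frame.

    Coordinates come from the chemical-component dictionary bundled with
    biotite. The frame: base ring centroid at the origin, ring best-fit
    normal along +z, the glycosidic nitrogen direction along +x.
    """
    import biotite.structure.info as info

    from .geometry import best_fit_plane

    arr = info.residue(resname)
    keep = [
        i for i in range(arr.array_length())
        if arr.element[i] != "H" and arr.atom_name[i] != "OP3"
    ]
    names = tuple(arr.atom_name[i] for i in keep)
    coords = np.array([arr.coord[i] for i in keep], dtype=float)
    ring_names = PURINE_RING_ATOMS if is_purine(resname) else PYRIMIDINE_RING_ATOMS
    ring = np.array([coords[names.index(nm)] for nm in ring_names])
    plane = best_fit_plane(ring)
    coords = coords - ring.mean(axis=0)
    rot = _align_z(plane.normal).T  # brings the ring normal onto +z
    coords = coords @ rot.T
    n_gly = coords[names.index("N9" if is_purine(resname) else "N1")]
    ang = np.degrees(np.arctan2(n_gly[1], n_gly[0]))
    coords = coords @ _rz(-ang).T
    return names, coords


def _residue_from_template(
    resname: str, chain_id: str, seq: int, transform, bfactor: float = 10.0
) -> Residue:
    names, coords = nucleotide_template(resname)
    placed = transform(coords)
    atoms = [
        Atom(name=nm, element=_element_of(nm), position=p, bfactor=bfactor)
        for nm, p in zip(names, placed)
    ]
    return Residue(chain_id=chain_id, seq_number=seq, name=resname, atoms=atoms)


# ---------------------------------------------------------------------------
# idealized quadruplex


@lru_cache(maxsize=None)
def _tune_quartet_placement(target: float = 2.88, hbond_limit: float = 3.2):
    """Find (radius, in-plane rotation, flip) placing four guanines in a
    Hoogsteen-bonded quartet with four-fold symmetry about +z.

    The objective drives the donor-acceptor N1-O6 and N2-N7 distances of
    neighbouring copies to the canonical hydrogen-bond length while a soft
    steric term keeps all other interatomic contacts above van-der-Waals
    range (this rejects degenerate overlapping-ring solutions).

    Returns (r, psi, flipped, donor_direction) where donor_direction = +1
    when copy j donates to copy j+1 (counted counterclockwise).
    """
    from scipy.spatial.distance import cdist

    names, base = nucleotide_template("DG")
    idx = {nm: i for i, nm in enumerate(names)}
    base_names = set(PURINE_RING_ATOMS) | {"O6", "N2"}
    base_idx = [i for i, nm in enumerate(names) if nm in base_names]
    hb_pairs = {
        1: ((idx["N1"], idx["O6"]), (idx["N2"], idx["N7"])),
        -1: ((idx["O6"], idx["N1"]), (idx["N7"], idx["N2"])),
    }

    def copies(r, psi, flipped):
        c = base @ np.diag([1.0, -1.0, -1.0]).T if flipped else base
        c = c @ _rz(psi).T + np.array([r, 0.0, 0.0])
        return c, c @ _rz(90.0).T

    def objective(x, flipped, direction):
        a, b = copies(x[0], x[1], flipped)
        (i1, j1), (i2, j2) = hb_pairs[direction]
        d1 = np.linalg.norm(a[i1] - b[j1])
        d2 = np.linalg.norm(a[i2] - b[j2])
        # steric term over base atoms only (sugars may be rebuilt later)
        d = cdist(a[base_idx], b[base_idx])
        clash = np.clip(2.7 - d, 0.0, None)
        return (d1 - target) ** 2 + (d2 - target) ** 2 + 3.0 * float((clash**2).sum())

    best = None
    rs = np.arange(2.5, 7.01, 0.25)
    psis = np.arange(0.0, 360.0, 5.0)
    for flipped in (False, True):
        for direction in (1, -1):
            coarse = [
                (objective((r0, p0), flipped, direction), r0, p0)
                for r0 in rs
                for p0 in psis
            ]
            coarse.sort()
            for f0, r0, p0 in coarse[:3]:
                res = minimize(
                    objective, [r0, p0], args=(flipped, direction),
                    method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 600},
                )
                if best is None or res.fun < best[0]:
                    best = (res.fun, float(res.x[0]), float(res.x[1]), flipped, direction)
    _, r, psi, flipped, direction = best
    a, b = copies(r, psi, flipped)
    (i1, j1), (i2, j2) = hb_pairs[direction]
    d1 = float(np.linalg.norm(a[i1] - b[j1]))
    d2 = float(np.linalg.norm(a[i2] - b[j2]))
    if max(d1, d2) > hbond_limit:
        raise ConstructionError(
            f"quartet radius untunable: best Hoogsteen distances {d1:.2f}/{d2:.2f} A"
        )
    return r, psi, flipped, direction


@dataclass(frozen=True)
class QuadruplexSpec:
    """Blueprint of an idealized intramolecular quadruplex.

    Defaults mirror a parallel three-layer promoter-type quadruplex: ~30
    degrees of helical twist and 3.3 A rise per layer, single-nucleotide
    propeller loops planted "out", and channel cations between layers.
    """

    n_layers: int = 3
    twist: float = 30.0
    rise: float = 3.3
    loops: tuple[tuple[int, str], ...] = ((1, "out"), (1, "out"), (1, "out"))
    loop_resname: str = "DT"
    topology: str = "parallel"  # parallel | antiparallel
    place_channel_ions: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 2:
            raise ConstructionError("n_layers must be >= 2")
        if not (2.8 <= self.rise <= 4.5):
            raise ConstructionError(f"rise {self.rise} outside [2.8, 4.5] A")
        if len(self.loops) != 3:
            raise ConstructionError("an intramolecular quadruplex has exactly 3 loops")
        for length, category in self.loops:
            if not 1 <= length <= 5:
                raise ConstructionError(f"loop length {length} outside 1..5")
            if category not in ("up", "down", "out", "stack"):
                raise ConstructionError(f"unknown planted category {category!r}")
        if self.topology not in ("parallel", "antiparallel"):
            raise ConstructionError(f"unknown topology {self.topology!r}")

    # ground-truth bookkeeping -------------------------------------------------
    def tract_seq_numbers(self) -> list[list[int]]:
        out, seq = [], 1
        for j in range(4):
            out.append(list(range(seq, seq + self.n_layers)))
            seq += self.n_layers
            if j < 3:
                seq += self.loops[j][0]
        return out

    def loop_seq_numbers(self) -> list[list[int]]:
        out, seq = [], 1
        for j in range(3):
            seq += self.n_layers
            out.append(list(range(seq, seq + self.loops[j][0])))
            seq += self.loops[j][0]
        return out

    @property
    def n_nucleotides(self) -> int:
        return 4 * self.n_layers + sum(length for length, _ in self.loops)


def _loop_base_transform(position, normal, inplane_deg: float):
    rot = _align_z(normal) @ _rz(inplane_deg)

    def transform(coords):
        return coords @ rot.T + np.asarray(position)

    return transform


def build_quadruplex(spec: QuadruplexSpec) -> Structure:
    """Idealized quadruplex with exactly known geometry.

    Four guanine columns 90 degrees apart; layer l is rotated by l*twist and
    raised by l*rise along +z. The Hoogsteen radius is auto-tuned so that
    N1-O6 and N2-N7 donor-acceptor distances are canonical (<= 3.2 A). Loop
    bases are planted at positions that realize their prescribed orientation
    category with margin; channel cations sit on the axis midway between
    layers. The chain starts at the bottom of column 0, so the core axis
    (anchored at the 5'-most guanine) is +z and "up" means increasing z.
    """
    r, psi, flipped, direction = _tune_quartet_placement()
    names, base = nucleotide_template("DG")
    n = spec.n_layers
    top_z = (n - 1) * spec.rise

    def guanine_transform(column: int, layer: int):
        def transform(coords):
            c = coords @ np.diag([1.0, -1.0, -1.0]).T if flipped else coords
            c = c @ _rz(psi).T + np.array([r, 0.0, 0.0])
            c = c @ _rz(90.0 * column + spec.twist * layer).T
            return c + np.array([0.0, 0.0, spec.rise * layer])

        return transform

    # column traversal order per tract
    if spec.topology == "parallel":
        layer_orders = [list(range(n))] * 4
    else:
        layer_orders = [list(range(n)), list(range(n - 1, -1, -1))] * 2

    residues: list[Residue] = []
    seq = 0
    rng = np.random.default_rng(spec.seed)
    guanine_of: dict[tuple[int, int], int] = {}  # (column, layer) -> seq number

    for column in range(4):
        for layer in layer_orders[column]:
            seq += 1
            residues.append(
                _residue_from_template("DG", "A", seq, guanine_transform(column, layer))
            )
            guanine_of[(column, layer)] = seq
        if column == 3:
            break
        length, category = spec.loops[column]
        # face the loop leaves from: the layer the tract just ended on
        exit_layer = layer_orders[column][-1]
        face_z = exit_layer * spec.rise
        # radial direction bisecting the two columns the loop connects
        theta = 90.0 * column + 45.0
        for m in range(length):
            seq += 1
            stagger = 25.0 * m - 12.5 * (length - 1)
            u = _rz(theta + stagger) @ np.array([1.0, 0.0, 0.0])
            if category == "out":
                pos = 11.0 * u + np.array([0.0, 0.0, face_z])
                normal = u  # ring roughly containing the axis direction
            elif category == "up":
                pos = 2.0 * u + np.array([0.0, 0.0, top_z + 5.0 + 0.8 * m])
                normal = np.array([0.0, 0.0, 1.0])
            elif category == "down":
                pos = 2.0 * u + np.array([0.0, 0.0, -5.0 - 0.8 * m])
                normal = np.array([0.0, 0.0, 1.0])
            else:  # stack: pile on the top guanine of the column just finished
                anchor_seq = guanine_of[(column, n - 1)]
                anchor = next(res for res in residues if res.seq_number == anchor_seq)
                from .quartets import ring_centroid

                pos = ring_centroid(anchor) + np.array([0.0, 0.0, 3.4 * (m + 1)])
                normal = np.array([0.0, 0.0, 1.0])
            inplane = float(rng.uniform(0.0, 360.0))
            residues.append(
                _residue_from_template(
                    spec.loop_resname, "A", seq,
                    _loop_base_transform(pos, normal, inplane),
                )
            )

    if spec.place_channel_ions:
        for gap in range(n - 1):
            seq += 1
            residues.append(
                Residue(
                    chain_id="A", seq_number=seq, name="K", is_hetero=True,
                    atoms=[Atom(name="K", element="K",
                                position=np.array([0.0, 0.0, (gap + 0.5) * spec.rise]))],
                )
            )
    return Structure(model_id=1, chains={"A": residues})


def build_bdna_duplex(n_bp: int = 8, twist: float = 36.0, rise: float = 3.4) -> Structure:
    """Idealized B-form G:C duplex — negative control for quartet detection.

    Guanines on chain A, cytosines on chain B facing them across the helix
    axis. Contains plenty of guanines but no Hoogsteen hydrogen-bond cycle.
    """
    g_names, _ = nucleotide_template("DG")
    strand_a, strand_b = [], []
    for i in range(n_bp):
        z = i * rise
        phi = i * twist

        def transform_g(coords, phi=phi, z=z):
            c = coords @ _rz(0.0).T + np.array([4.25, 0.0, 0.0])
            return c @ _rz(phi).T + np.array([0.0, 0.0, z])

        def transform_c(coords, phi=phi, z=z):
            # opposite strand: flipped base across the pseudo-dyad
            c = coords @ np.diag([1.0, -1.0, -1.0]).T + np.array([4.25, 0.0, 0.0])
            return c @ _rz(phi + 180.0).T + np.array([0.0, 0.0, z])

        strand_a.append(_residue_from_template("DG", "A", i + 1, transform_g))
        strand_b.append(_residue_from_template("DC", "B", i + 1, transform_c))
    return Structure(model_id=1, chains={"A": strand_a, "B": list(reversed(strand_b))})


# ---------------------------------------------------------------------------
# perturbation ensembles and planted trajectories


def copy_structure(structure: Structure, model_id: int | None = None) -> Structure:
    out = copy.deepcopy(structure)
    if model_id is not None:
        out.model_id = model_id
    return out


@dataclass(frozen=True)
class PerturbationSpec:
    """Gaussian ensemble blueprint: per-residue sigma (A, per coordinate)."""

    sigma_profile: dict[int, float] | float
    n_members: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 2:
            raise ConstructionError("n_members must be >= 2")
        sigmas = (
            self.sigma_profile.values()
            if isinstance(self.sigma_profile, dict)
            else [self.sigma_profile]
        )
        if any(s < 0 for s in sigmas):
            raise ConstructionError("sigma must be nonnegative")

    def sigma_for(self, seq_number: int) -> float:
        if isinstance(self.sigma_profile, dict):
            return float(self.sigma_profile.get(seq_number, 0.0))
        return float(self.sigma_profile)


def perturb_ensemble(ref: Structure, spec: PerturbationSpec) -> Ensemble:
    """i.i.d. Gaussian coordinate noise on a reference, seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    members = []
    for m in range(spec.n_members):
        member = copy_structure(ref, model_id=m + 1)
        for res in member.residues():
            sigma = spec.sigma_for(res.seq_number)
            for atom in res.atoms:
                if sigma > 0:
                    atom.position = atom.position + rng.normal(0.0, sigma, 3)
        members.append(member)
    return Ensemble(members=members)


@dataclass(frozen=True)
class TrajectorySpec:
    """Planted-cluster trajectories: centers, noise, per-trajectory schedule."""

    noise_sigma: float = 0.1
    schedule: tuple[tuple[int, ...], ...] = ((0, 0, 1, 1), (1, 0, 0, 1))
    seed: int = 0

    def __post_init__(self):
        if len(self.schedule) < 1:
            raise ConstructionError("need at least one trajectory")

    @property
    def n_switches(self) -> int:
        return sum(
            sum(1 for a, b in zip(traj, traj[1:]) if a != b) for traj in self.schedule
        )


def make_cluster_centers(
    ref: Structure, k: int, deform_sigma: float = 1.5, seed: int = 0
) -> list[Structure]:
    """Distinct conformations made by Gaussian deformation of a reference.

    Deformation (not rigid motion!) separates the centers under fitted RMSD:
    two centers differ by about deform_sigma * sqrt(6) A after fitting.
    """
    rng = np.random.default_rng(seed)
    centers = []
    for c in range(k):
        center = copy_structure(ref, model_id=c + 1)
        for res in center.residues():
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, deform_sigma, 3)
        centers.append(center)
    return centers


def generate_trajectories(centers: list[Structure], spec: TrajectorySpec) -> Ensemble:
    """Frame t of trajectory r = centers[schedule[r][t]] + noise.

    Frames carry trajectory ids in ``source_labels`` so transition counting
    can respect run boundaries.
    """
    for traj in spec.schedule:
        for label in traj:
            if not 0 <= label < len(centers):
                raise ConstructionError(
                    f"schedule references center {label}, only {len(centers)} given"
                )
    rng = np.random.default_rng(spec.seed)
    members, labels = [], []
    model_id = 0
    for r, traj in enumerate(spec.schedule):
        for t, center_idx in enumerate(traj):
            model_id += 1
            frame = copy_structure(centers[center_idx], model_id=model_id)
            for res in frame.residues():
                for atom in res.atoms:
                    if spec.noise_sigma > 0:
                        atom.position = atom.position + rng.normal(0.0, spec.noise_sigma, 3)
            members.append(frame)
            labels.append(str(r))
    return Ensemble(members=members, source_labels=labels)
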