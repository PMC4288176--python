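"""Hierarchical atomic model and coordinate-file I/O.

The in-memory model is deliberately small: ``Ensemble`` -> ``Structure``
(one per MODEL record) -> chains -> ``Residue`` -> ``Atom``. Parsing and
PDB writing are delegated to gemmi; this module adds the policies the
analyses rely on (altloc resolution by occupancy, primed-atom-name
normalization, residue-name normalization across DNA/RNA/one-letter
depositions, optional hydrogen stripping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "ParseError",
    "EmptyEnsembleError",
    "StructureLookupError",
    "read_structures",
    "write_pdb",
    "structure_summary",
    "write_summary_json",
    "count_residue_class",
    "extract_chain",
    "base_code",
    "is_nucleotide",
    "is_purine",
    "is_pyrimidine",
    "sequential_index",
]


class ParseError(ValueError):
    """A coordinate file could not be parsed under the named standard."""


class EmptyEnsembleError(ValueError):
    """The file parsed but contained no coordinate models."""


class StructureLookupError(KeyError):
    """A requested model/chain/residue/atom does not exist."""


# residue-name normalization: deoxy, ribo and one-letter deposition variants
# all map to one-letter base codes so NMR and X-ray entries compare directly.
_BASE_CODES = {
    "DA": "A", "DG": "G", "DC": "C", "DT": "T", "DU": "U",
    "A": "A", "G": "G", "C": "C", "T": "T", "U": "U",
    "ADE": "A", "GUA": "G", "CYT": "C", "THY": "T", "URA": "U",
    "BRU": "T",  # 5-bromo-dU: thymine analogue at position 12 of the BrU entry
}
_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T", "U"}


def base_code(residue_name: str) -> str | None:
    """One-letter base code for a residue name, or None for non-nucleotides."""
    return _BASE_CODES.get(residue_name.strip().upper())


def is_nucleotide(residue_name: str) -> bool:
    return base_code(residue_name) is not None


def is_purine(residue_name: str) -> bool:
    return base_code(residue_name) in _PURINES


def is_pyrimidine(residue_name: str) -> bool:
    return base_code(residue_name) in _PYRIMIDINES


def _normalize_atom_name(name: str) -> str:
    """Map old-style primed names (O5*, C1*) onto the PDB v3 convention."""
    return name.strip().replace("*", "'")


@dataclass
class Atom:
    """A single atom: PDB-convention name, element, position (A), B (A^2)."""

    name: str
    element: str
    position: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite position")
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B factor")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        name = _normalize_atom_name(name)
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stacked positions; with ``names``, in that order (all must exist)."""
        if names is None:
            return np.array([a.position for a in self.atoms], dtype=float)
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise StructureLookupError(
                    f"residue {self.name}{self.seq_number}: no atom {n!r}"
                )
            out.append(a.position)
        return np.array(out, dtype=float)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_number)

    @property
    def label(self) -> str:
        code = base_code(self.name) or self.name
        return f"{code}{self.seq_number}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain_id}/{self.name}{self.seq_number} ({len(self.atoms)} atoms)>"


@dataclass
class Structure:
    """One coordinate model: ordered chains of ordered residues."""

    model_id: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise StructureLookupError(
                f"no chain {chain_id!r}; available: {sorted(self.chains)}"
            ) from None

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is None:
            for residues in self.chains.values():
                yield from residues
        else:
            yield from self.chain(chain_id)

    def residue(self, chain_id: str, seq_number: int) -> Residue:
        for r in self.chain(chain_id):
            if r.seq_number == seq_number:
                return r
        raise StructureLookupError(f"no residue {seq_number} in chain {chain_id!r}")

    def nucleotides(self, chain_id: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain_id) if is_nucleotide(r.name)]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass
class Ensemble:
    """Ordered structures sharing one chain/residue layout.

    ``source_labels`` optionally tags each member with a trajectory or run
    identifier; consecutive members with equal labels are treated as
    consecutive frames of one trajectory by the clustering module.
    """

    members: list[Structure]
    source_labels: list[str] | None = None

    def __post_init__(self):
        if not self.members:
            raise EmptyEnsembleError("ensemble must contain at least one structure")
        if self.source_labels is not None and len(self.source_labels) != len(self.members):
            raise ValueError("source_labels must pair 1:1 with members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.members)

    def __getitem__(self, i) -> Structure:
        return self.members[i]

    def layout(self) -> list[tuple[str, int, str]]:
        return [(r.chain_id, r.seq_number, r.name) for r in self.members[0].residues()]

    def assert_shared_layout(self) -> None:
        ref = self.layout()
        for m in self.members[1:]:
            lay = [(r.chain_id, r.seq_number, r.name) for r in m.residues()]
            if lay != ref:
                raise ValueError(
                    f"model {m.model_id} does not share the layout of model "
                    f"{self.members[0].model_id}"
                )


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in res:
        key = _normalize_atom_name(at.name)
        prev = by_name.get(key)
        if prev is None or at.occ > prev.occ + 1e-9:
            by_name[key] = at
    return list(by_name.values())


def _convert_model(model: gemmi.Model, model_id: int, drop_hydrogens: bool) -> Structure:
    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues = chains.setdefault(ch.name, [])
        for res in ch:
            atoms = []
            for at in _resolve_altlocs(res):
                if drop_hydrogens and at.element.name in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=_normalize_atom_name(at.name),
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        bfactor=max(float(at.b_iso), 0.0),
                        occupancy=float(at.occ),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=ch.name,
                        seq_number=res.seqid.num,
                        name=res.name.strip(),
                        atoms=atoms,
                        is_hetero=(res.het_flag == "H"),
                    )
                )
    return Structure(model_id=model_id, chains={k: v for k, v in chains.items() if v})


def read_structures(
    path: str | Path,
    format: str = "auto",
    drop_hydrogens: bool = True,
) -> Ensemble:
    """Read a PDB or mmCIF file into an :class:`Ensemble`.

    Every MODEL record becomes one member. HETATM waters and ions are
    retained with ``is_hetero`` set. Alternate locations are resolved to the
    highest-occupancy conformer (ties: first in file). Hydrogens are dropped
    by default — all downstream geometry is hydrogen-free so that crystal
    structures (no H) and NMR depositions (with H) are treated uniformly.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt not in ("auto", "pdb", "mmcif"):
        raise ValueError(f"format must be pdb, mmcif or auto, not {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        # gemmi error messages carry the offending line/token
        raise ParseError(f"failed to parse {path.name}: {exc}") from exc
    members = []
    for i, model in enumerate(st):
        try:
            model_id = int(model.num)
        except (AttributeError, ValueError, TypeError):
            model_id = i + 1
        converted = _convert_model(model, model_id, drop_hydrogens)
        if converted.chains:
            members.append(converted)
    if not members:
        raise EmptyEnsembleError(f"{path.name}: no coordinate models found")
    return Ensemble(members=members)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(ensemble: Ensemble, name: str = "quadgeom") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for member in ensemble:
        model = gemmi.Model(member.model_id)
        for chain_id, residues in member.chains.items():
            chain = gemmi.Chain(chain_id)
            for r in residues:
                res = gemmi.Residue()
                res.name = r.name
                res.seqid = gemmi.SeqId(r.seq_number, " ")
                res.het_flag = "H" if r.is_hetero else "A"
                for a in r.atoms:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.element = gemmi.Element(a.element)
                    at.pos = gemmi.Position(*a.position)
                    at.occ = a.occupancy
                    at.b_iso = a.bfactor
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(ensemble: Ensemble | Structure, path: str | Path) -> None:
    """Write fixed-column PDB (3-decimal coordinates) via gemmi."""
    if isinstance(ensemble, Structure):
        ensemble = Ensemble(members=[ensemble])
    _to_gemmi(ensemble).write_pdb(str(path))


def structure_summary(ensemble: Ensemble) -> dict:
    """JSON-ready inventory: models, chains, residue and atom counts."""
    first = ensemble.members[0]
    return {
        "n_models": len(ensemble),
        "chains": {
            cid: {
                "n_residues": len(res),
                "n_nucleotides": sum(is_nucleotide(r.name) for r in res),
                "n_atoms": sum(len(r.atoms) for r in res),
                "sequence": "".join(base_code(r.name) or "" for r in res),
            }
            for cid, res in first.chains.items()
        },
        "source_labels": ensemble.source_labels,
    }


def write_summary_json(ensemble: Ensemble, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_summary(ensemble), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# queries

_CLASS_NAMES = {
    "water": _WATER_NAMES,
    "potassium": {"K", "K+"},
    "magnesium": {"MG", "MG2", "MG+2"},
}


def count_residue_class(structure: Structure, residue_class: str) -> int:
    """Count residues of a named class: water, potassium, magnesium, nucleotide."""
    cls = residue_class.lower()
    if cls == "nucleotide":
        return sum(1 for r in structure.residues() if is_nucleotide(r.name))
    try:
        names = _CLASS_NAMES[cls]
    except KeyError:
        raise ValueError(
            f"unknown residue class {residue_class!r}; "
            f"expected one of {sorted(_CLASS_NAMES) + ['nucleotide']}"
        ) from None
    return sum(1 for r in structure.residues() if r.name.upper() in names)


def extract_chain(ensemble: Ensemble, model_id: int, chain_id: str) -> Structure:
    """Single-chain :class:`Structure` with original author numbering."""
    for member in ensemble:
        if member.model_id == model_id:
            break
    else:
        raise StructureLookupError(
            f"no model {model_id}; available: {[m.model_id for m in ensemble]}"
        )
    residues = member.chain(chain_id)
    return Structure(model_id=model_id, chains={chain_id: list(residues)})


def sequential_index(chain: Iterable[Residue]) -> dict[tuple[str, int], int]:
    """Sequential nucleotide numbering (1..n from the 5' end) per residue key.

    Deposited entries keep author numbering; analyses and reports that need
    the uniform 1-22-from-the-5'-adenosine labelling use this mapping.
    """
    out: dict[tuple[str, int], int] = {}
    i = 0
    for r in chain:
        if is_nucleotide(r.name):
            i += 1
            out[r.key] = i
    return out
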