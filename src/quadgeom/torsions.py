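"""Standard nucleic-acid backbone and glycosidic torsions.

Per residue i (IUPAC definitions, degrees, range (-180, 180]):

    alpha:   O3'(i-1) - P(i)   - O5'(i) - C5'(i)
    beta:    P(i)     - O5'(i) - C5'(i) - C4'(i)
    gamma:   O5'(i)   - C5'(i) - C4'(i) - C3'(i)
    delta:   C5'(i)   - C4'(i) - C3'(i) - O3'(i)
    epsilon: C4'(i)   - C3'(i) - O3'(i) - P(i+1)
    zeta:    C3'(i)   - O3'(i) - P(i+1) - O5'(i+1)
    chi:     O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)

Angles whose atoms are absent (chain termini, disordered atoms) are None,
never an exception: a 5'-terminal residue without a phosphate has no
alpha/beta, a 3'-terminal residue no epsilon/zeta.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .geometry import GeometryError, dihedral
from .structures import Residue, Structure, is_purine, sequential_index

__all__ = ["TorsionRecord", "TORSION_NAMES", "backbone_torsions", "torsion_table"]

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@dataclass(frozen=True)
class TorsionRecord:
    residue: Residue
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in TORSION_NAMES}


def _pos(residue: Residue | None, atom_name: str):
    if residue is None:
        return None
    atom = residue.atom(atom_name)
    return None if atom is None else atom.position


def _torsion(*points) -> float | None:
    if any(p is None for p in points):
        return None
    try:
        return dihedral(*points)
    except GeometryError:
        return None


def backbone_torsions(chain: Structure, chain_id: str | None = None) -> list[TorsionRecord]:
    """Compute the seven standard torsions for every nucleotide of a chain.

    ``chain`` may hold several chains; ``chain_id`` selects one (required in
    that case). Consecutive nucleotides in file order are treated as bonded
    neighbours.
    """
    if chain_id is None:
        ids = list(chain.chains)
        if len(ids) != 1:
            raise ValueError(f"structure has chains {ids}; pass chain_id")
        chain_id = ids[0]
    nts = chain.nucleotides(chain_id)
    records = []
    for i, res in enumerate(nts):
        prev = nts[i - 1] if i > 0 else None
        nxt = nts[i + 1] if i + 1 < len(nts) else None
        p, o5, c5, c4, c3, o3 = (
            _pos(res, n) for n in ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
        )
        o3_prev = _pos(prev, "O3'")
        p_next = _pos(nxt, "P")
        o5_next = _pos(nxt, "O5'")
        if is_purine(res.name):
            chi = _torsion(_pos(res, "O4'"), _pos(res, "C1'"), _pos(res, "N9"), _pos(res, "C4"))
        else:
            chi = _torsion(_pos(res, "O4'"), _pos(res, "C1'"), _pos(res, "N1"), _pos(res, "C2"))
        records.append(
            TorsionRecord(
                residue=res,
                alpha=_torsion(o3_prev, p, o5, c5),
                beta=_torsion(p, o5, c5, c4),
                gamma=_torsion(o5, c5, c4, c3),
                delta=_torsion(c5, c4, c3, o3),
                epsilon=_torsion(c4, c3, o3, p_next),
                zeta=_torsion(c3, o3, p_next, o5_next),
                chi=chi,
            )
        )
    return records


_LABEL_RE = re.compile(r"^([ACGTU]?)(\d+)$", re.IGNORECASE)


def _parse_selection(residues) -> list[tuple[str | None, int]]:
    out = []
    for item in residues:
        if isinstance(item, int):
            out.append((None, item))
            continue
        m = _LABEL_RE.match(str(item).strip())
        if not m:
            raise ValueError(
                f"residue selector {item!r} not understood; use e.g. 'A1', 'C9' or 9"
            )
        out.append((m.group(1).upper() or None, int(m.group(2))))
    return out


def torsion_table(
    ensembles: list[tuple[str, Structure]],
    residues,
    chain_ids: list[str | None] | None = None,
) -> pd.DataFrame:
    """Cross-structure torsion comparison table.

    Rows are (residue label, angle) pairs; one column per labelled structure.
    ``residues`` selects by sequential 5'->3' position (``9``) or by
    base-plus-position label (``"C9"``, checked against the sequence).
    Undefined torsions are left as NaN (blank cells on CSV export).
    """
    if not ensembles:
        raise ValueError("no structures given")
    labels = [lab for lab, _ in ensembles]
    if len(set(labels)) != len(labels):
        raise ValueError(f"structure labels must be unique, got {labels}")
    selectors = _parse_selection(residues)
    if not selectors:
        raise ValueError("empty residue selection")
    if chain_ids is None:
        chain_ids = [None] * len(ensembles)

    columns: dict[str, dict[tuple[str, str], float]] = {}
    row_order: list[tuple[str, str]] = []
    for (label, structure), cid in zip(ensembles, chain_ids):
        recs = backbone_torsions(structure, cid)
        seqidx = sequential_index(structure.nucleotides(cid))
        by_pos = {seqidx[r.residue.key]: r for r in recs}
        col: dict[tuple[str, str], float] = {}
        for base, pos in selectors:
            rec = by_pos.get(pos)
            if rec is None:
                raise ValueError(f"{label}: no nucleotide at sequential position {pos}")
            res_label = rec.residue.label
            code = res_label.rstrip("0123456789") or "?"
            if base is not None and code.upper() != base:
                raise ValueError(
                    f"{label}: position {pos} is {code}, selector asked for {base}"
                )
            row_label = f"{code}{pos}"
            for angle, value in rec.as_dict().items():
                key = (row_label, angle)
                if key not in row_order and label == labels[0]:
                    row_order.append(key)
                if value is not None:
                    col[key] = value
        columns[label] = col

    # rows follow the first structure's selection order
    index = pd.MultiIndex.from_tuples(row_order, names=["residue", "angle"])
    table = pd.DataFrame(index=index, columns=labels, dtype=float)
    for label in labels:
        for key, value in columns[label].items():
            if key in index:
                table.loc[key, label] = value
    return table
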