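"""Orientation of extra-helical bases relative to the quartet core.

Every base outside the stacked core is called one of four categories with
respect to the core reference frame: ``up`` (toward the far end of the core
axis), ``down`` (toward the 5'-anchored bottom face), ``out`` (swung away
from the core, roughly in the quartet plane) or ``stack`` (pi-stacked on a
core guanine or on another extra-helical base). The thresholds default to
canonical pi-stacking geometry and are explicit parameters so sensitivity
can be scanned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import best_fit_plane
from .quartets import QuartetCore, ring_coords
from .structures import Ensemble, Residue, Structure, StructureLookupError

__all__ = [
    "ORIENTATION_CATEGORIES",
    "OrientationCall",
    "CleftMeasurement",
    "ClassificationError",
    "classify_base_orientation",
    "occupancy_table",
    "orientation_summary",
    "cleft_width",
]

ORIENTATION_CATEGORIES = ("up", "down", "out", "stack")


class ClassificationError(ValueError):
    """A base cannot be classified (e.g. missing ring atoms)."""


@dataclass(frozen=True)
class OrientationCall:
    residue: Residue
    category: str
    stack_partner: Residue | None
    axial_component: float
    radial_component: float
    elevation_angle: float

    def __post_init__(self):
        assert (self.category == "stack") == (self.stack_partner is not None)


def _ring_geometry(residue: Residue):
    pts = ring_coords(residue)
    if len(pts) < 3:
        raise ClassificationError(
            f"residue {residue.label}: fewer than 3 ring atoms present"
        )
    plane = best_fit_plane(pts)
    return pts.mean(axis=0), plane.normal


def _is_stacked(
    centroid, normal, partner_centroid, partner_normal,
    lateral_max: float, axial_window: tuple[float, float], plane_angle_max: float,
) -> bool:
    delta = centroid - partner_centroid
    axial = abs(float(delta @ partner_normal))
    lateral = float(np.linalg.norm(delta - (delta @ partner_normal) * partner_normal))
    cosang = abs(float(np.dot(normal, partner_normal)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return (
        axial_window[0] <= axial <= axial_window[1]
        and lateral <= lateral_max
        and angle <= plane_angle_max
    )


def classify_base_orientation(
    base: Residue,
    core: QuartetCore,
    stack_candidates: list[Residue] | None = None,
    stack_lateral_max: float = 2.5,
    stack_axial_window: tuple[float, float] = (3.0, 4.2),
    elevation_cut: float = 30.0,
    plane_angle_max: float = 30.0,
) -> OrientationCall:
    """Classify one extra-helical base as up/down/out/stack.

    The base ring centroid is decomposed relative to the nearest layer
    centroid into a signed axial component (along the core axis, + = toward
    the top face) and a radial component. Stacking against core guanines
    plus any ``stack_candidates`` (e.g. other loop bases) takes precedence;
    otherwise elevation = atan2(axial, radial) decides up/down/out.
    """
    centroid, normal = _ring_geometry(base)
    partners = [g for q in core.layers for g in q.guanines]
    if stack_candidates:
        partners += [r for r in stack_candidates if r.key != base.key]
    best_partner, best_dist = None, np.inf
    for partner in partners:
        try:
            pc, pn = _ring_geometry(partner)
        except ClassificationError:
            continue
        if _is_stacked(centroid, normal, pc, pn,
                       stack_lateral_max, stack_axial_window, plane_angle_max):
            d = float(np.linalg.norm(centroid - pc))
            if d < best_dist:
                best_partner, best_dist = partner, d

    axial, radial, _ = core.axial_radial(centroid)
    elevation = float(np.degrees(np.arctan2(axial, radial)))
    if best_partner is not None:
        category = "stack"
    elif elevation > elevation_cut:
        category = "up"
    elif elevation < -elevation_cut:
        category = "down"
    else:
        category = "out"
    return OrientationCall(
        residue=base,
        category=category,
        stack_partner=best_partner if category == "stack" else None,
        axial_component=axial,
        radial_component=radial,
        elevation_angle=elevation,
    )


def occupancy_table(
    calls_per_member: list[dict[str, str]],
    weights: list[float] | None = None,
) -> pd.DataFrame:
    """Per-base category occupancy (%) from per-member classification dicts.

    ``calls_per_member`` holds one ``{base label: category}`` dict per
    member (or per cluster medoid); optional ``weights`` (e.g. cluster
    populations) must sum to 1. Rows sum to 100 within rounding.
    """
    if not calls_per_member:
        raise ValueError("no classifications given")
    n = len(calls_per_member)
    if weights is None:
        weights = [1.0 / n] * n
    if len(weights) != n:
        raise ValueError("weights must pair 1:1 with members")
    if abs(sum(weights) - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {sum(weights)!r}, expected 1")
    bases = list(calls_per_member[0])
    table = pd.DataFrame(0.0, index=bases, columns=list(ORIENTATION_CATEGORIES))
    for member, w in zip(calls_per_member, weights):
        for base in bases:
            cat = member.get(base)
            if cat not in ORIENTATION_CATEGORIES:
                raise ValueError(f"member lacks a valid category for base {base!r}: {cat!r}")
            table.loc[base, cat] += 100.0 * w
    return table


def orientation_summary(
    ensemble: Ensemble,
    bases: list[int],
    chain_id: str | None = None,
    weights: list[float] | None = None,
    **thresholds,
) -> pd.DataFrame:
    """Category occupancy (%) of selected bases across an ensemble.

    For every member the quartet core is rebuilt and each selected base
    (author seq numbers) is classified; other selected bases of the same
    member serve as stacking candidates. Optional ``weights`` (one per
    member, summing to 1) reproduce population-weighted reporting, e.g.
    weighting cluster medoids by cluster populations.
    """
    from .quartets import build_core, detect_quartets

    if not bases:
        raise ValueError("empty base selection")
    calls: list[dict[str, str]] = []
    for member in ensemble:
        cid = chain_id or next(iter(member.chains))
        core = build_core(detect_quartets(member))
        selected = [member.residue(cid, int(s)) for s in bases]
        member_calls = {}
        for res in selected:
            call = classify_base_orientation(
                res, core, stack_candidates=selected, **thresholds
            )
            member_calls[res.label] = call.category
        calls.append(member_calls)
    return occupancy_table(calls, weights)


@dataclass(frozen=True)
class CleftMeasurement:
    residue_a: Residue
    residue_b: Residue
    distance: float  # P...P separation, Angstrom

    @property
    def label(self) -> str:
        return f"P({self.residue_a.label})...P({self.residue_b.label})"


def cleft_width(structure: Structure, res_a, res_b, chain_id: str | None = None) -> CleftMeasurement:
    """Inter-strand P...P separation across a cleft, Angstrom.

    ``res_a``/``res_b`` are residues or (chain_id given) author seq numbers.
    Reported to 1 decimal in human-readable tables; the raw value is exact.
    """
    def resolve(item) -> Residue:
        if isinstance(item, Residue):
            return item
        if chain_id is None:
            raise ValueError("pass chain_id when selecting residues by number")
        return structure.residue(chain_id, int(item))

    ra, rb = resolve(res_a), resolve(res_b)
    pa, pb = ra.atom("P"), rb.atom("P")
    for res, atom in ((ra, pa), (rb, pb)):
        if atom is None:
            raise StructureLookupError(f"residue {res.label} has no phosphorus atom")
    return CleftMeasurement(
        residue_a=ra,
        residue_b=rb,
        distance=float(np.linalg.norm(pa.position - pb.position)),
    )
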