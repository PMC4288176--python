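"""Per-residue flexibility profiles.

Three sources are put on a common footing so they can be compared across
techniques: crystallographic isotropic B factors averaged per residue,
root-mean-square fluctuations (RMSF) of an ensemble about its superposed
mean, and theoretical B factors derived from RMSF via B = (8 pi^2 / 3) <dr^2>.
"Normalized" means a per-chain z-score by default (min-max scaling is
available for figure-style replotting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .geometry import superpose
from .quartets import QuartetCore, ring_atom_names
from .structures import Atom, Ensemble, Residue, Structure, is_nucleotide

__all__ = [
    "FlexibilityProfile",
    "residue_bfactors",
    "normalize_profile",
    "ensemble_rmsf",
    "rmsf_to_bfactor",
    "theoretical_bfactors",
    "compare_profiles",
    "core_guanine_selection",
]

AtomSelection = Callable[[Residue, Atom], bool]

B_FROM_MSF = 8.0 * np.pi**2 / 3.0


@dataclass(frozen=True)
class FlexibilityProfile:
    """Ordered per-residue (or per-atom) flexibility values.

    ``raw_values`` are A^2 for B factors and A for RMSF; ``normalized_values``
    is filled by :func:`normalize_profile`.
    """

    labels: tuple[str, ...]
    raw_values: np.ndarray
    source: str  # crystal_b | ensemble_rmsf | theoretical_b
    normalized_values: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "raw_values", np.asarray(self.raw_values, dtype=float))
        if len(self.labels) != len(self.raw_values):
            raise ValueError("labels and values must pair 1:1")

    @property
    def values(self) -> np.ndarray:
        return self.normalized_values if self.normalized_values is not None else self.raw_values

    def as_frame(self) -> pd.DataFrame:
        data = {"label": list(self.labels), "raw": self.raw_values}
        if self.normalized_values is not None:
            data["normalized"] = self.normalized_values
        return pd.DataFrame(data)


def residue_bfactors(
    structure: Structure,
    atom_scope: str = "all",
    chain_id: str | None = None,
) -> FlexibilityProfile:
    """Unweighted per-residue mean of atomic B factors over the scope.

    ``atom_scope='base_only'`` restricts the mean to base ring atoms.
    Nucleotide residues only; a residue with an empty scope is dropped.
    """
    if atom_scope not in ("all", "base_only"):
        raise ValueError(f"atom_scope must be 'all' or 'base_only', not {atom_scope!r}")
    labels, values = [], []
    for res in structure.nucleotides(chain_id):
        atoms = res.atoms
        if atom_scope == "base_only":
            names = ring_atom_names(res)
            atoms = [a for a in atoms if a.name in names]
        if not atoms:
            continue
        labels.append(res.label)
        values.append(float(np.mean([a.bfactor for a in atoms])))
    return FlexibilityProfile(tuple(labels), np.array(values), source="crystal_b")


def normalize_profile(profile: FlexibilityProfile, mode: str = "zscore") -> FlexibilityProfile:
    """Normalize a profile over its residues.

    ``zscore`` (default): (x - mean) / sd with population sd; a constant
    profile maps to all zeros. ``minmax`` rescales onto [0, 1]. Normalizing
    an already-normalized profile is a no-op (idempotent).
    """
    x = profile.values.astype(float)
    if len(x) < 2:
        raise ValueError("normalization needs at least 2 values")
    if mode == "zscore":
        sd = float(np.std(x))
        norm = np.zeros_like(x) if sd < 1e-12 else (x - np.mean(x)) / sd
    elif mode == "minmax":
        span = float(np.ptp(x))
        norm = np.zeros_like(x) if span < 1e-12 else (x - np.min(x)) / span
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(profile, normalized_values=norm)


def core_guanine_selection(core: QuartetCore) -> AtomSelection:
    """Atom selection covering the heavy atoms of the core guanines.

    Default fit selection for :func:`ensemble_rmsf`: fitting on the stable
    quartet core keeps loop flexibility from being absorbed by the fit.
    """
    keys = core.core_keys()

    def select(res: Residue, atom: Atom) -> bool:
        return res.key in keys

    return select


def _flat_atoms(structure: Structure) -> list[tuple[Residue, Atom]]:
    return [(r, a) for r in structure.residues() for a in r.atoms]


def ensemble_rmsf(
    ensemble: Ensemble,
    fit_selection: AtomSelection | None = None,
    per: str = "residue",
    max_iterations: int = 1,
) -> FlexibilityProfile:
    """RMSF of every atom about the superposed ensemble mean, in Angstrom.

    Each member is superposed onto the running mean structure using the fit
    selection (default: every atom); the mean is refined once (mean -> fit
    -> mean) unless ``max_iterations`` asks for more. RMSF(atom) =
    sqrt(mean_m |r_m - rbar|^2); per-residue values are the mean over the
    residue's atoms.
    """
    if per not in ("residue", "atom"):
        raise ValueError(f"per must be 'residue' or 'atom', not {per!r}")
    if len(ensemble) < 2:
        raise ValueError("RMSF needs an ensemble with at least 2 members")
    ensemble.assert_shared_layout()
    pairs = _flat_atoms(ensemble[0])
    if fit_selection is None:
        fit_idx = np.arange(len(pairs))
    else:
        fit_idx = np.array(
            [i for i, (r, a) in enumerate(pairs) if fit_selection(r, a)], dtype=int
        )
        if len(fit_idx) < 3:
            raise ValueError("fit selection must cover at least 3 atoms")

    coords = np.array(
        [[a.position for _, a in _flat_atoms(m)] for m in ensemble], dtype=float
    )
    mean = coords.mean(axis=0)
    for _ in range(max(1, max_iterations)):
        fitted = np.empty_like(coords)
        for m in range(coords.shape[0]):
            sup = superpose(coords[m, fit_idx], mean[fit_idx])
            fitted[m] = sup.apply(coords[m])
        new_mean = fitted.mean(axis=0)
        converged = np.allclose(new_mean, mean, atol=1e-10)
        coords, mean = fitted, new_mean
        if converged:
            break
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    atom_rmsf = np.sqrt(msf)

    if per == "atom":
        labels = tuple(f"{r.label}:{a.name}" for r, a in pairs)
        return FlexibilityProfile(labels, atom_rmsf, source="ensemble_rmsf")
    labels, values, start = [], [], 0
    for res in ensemble[0].residues():
        n = len(res.atoms)
        if is_nucleotide(res.name):
            labels.append(res.label)
            values.append(float(np.mean(atom_rmsf[start : start + n])))
        start += n
    return FlexibilityProfile(tuple(labels), np.array(values), source="ensemble_rmsf")


def rmsf_to_bfactor(rmsf) -> np.ndarray | float:
    """Theoretical isotropic B factor from RMSF: B = (8 pi^2 / 3) rmsf^2."""
    arr = np.asarray(rmsf, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RMSF must be nonnegative")
    out = B_FROM_MSF * arr**2
    return float(out) if out.ndim == 0 else out


def theoretical_bfactors(profile: FlexibilityProfile) -> FlexibilityProfile:
    """Convert an RMSF profile (A) to a theoretical-B profile (A^2)."""
    if profile.source != "ensemble_rmsf":
        raise ValueError("theoretical B factors derive from an RMSF profile")
    return FlexibilityProfile(
        profile.labels, rmsf_to_bfactor(profile.raw_values), source="theoretical_b"
    )


def compare_profiles(
    profiles: list[tuple[str, FlexibilityProfile]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side normalized profiles + Spearman rank correlation per pair.

    Profiles are aligned by sequential position (1..n along each profile);
    all profiles must cover the same number of positions.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    lengths = {len(p.raw_values) for _, p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles cover different index sets: lengths {sorted(lengths)}")
    normalized = {
        label: (p if p.normalized_values is not None else normalize_profile(p)).normalized_values
        for label, p in profiles
    }
    index = pd.RangeIndex(1, lengths.pop() + 1, name="position")
    table = pd.DataFrame(normalized, index=index)
    labels = list(table.columns)
    corr = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rho = spearmanr(table[a], table[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = float(rho)
    return table, corr
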