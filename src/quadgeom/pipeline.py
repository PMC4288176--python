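"""End-to-end analysis: coordinate files in, report bundle out.

For each input structure the pipeline emits, per quadruplex-bearing chain,
a topology JSON (quartets, core, channel ions, loops), a torsion CSV, an
orientation JSON and a flexibility CSV, plus cleft P...P distances; for
multi-model inputs it adds an RMSF CSV and, with enough frames, a medoid
clustering with its transition graph. Reports are deterministic under a
fixed config and seed: JSON keys are sorted and floats fixed at 4 decimals
(1 decimal for Angstrom distances in the human-readable cleft table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__ as _version
from .clustering import cluster_medoids, distance_matrix, select_k, transition_graph
from .config import AnalysisConfig
from .flexibility import (
    core_guanine_selection,
    ensemble_rmsf,
    normalize_profile,
    residue_bfactors,
)
from .orientation import classify_base_orientation, cleft_width
from .quartets import assign_ions, build_core, classify_topology, detect_quartets
from .structures import Ensemble, Structure, read_structures, sequential_index
from .torsions import torsion_table

__all__ = ["AnalysisResult", "analyze", "analyze_chain"]

log = logging.getLogger("quadgeom")


def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(data), indent=2, sort_keys=True) + "\n")


@dataclass
class AnalysisResult:
    out_dir: Path
    reports: dict[str, list[str]] = field(default_factory=dict)  # input -> files
    failures: dict[str, str] = field(default_factory=dict)       # input -> error

    @property
    def all_failed(self) -> bool:
        return bool(self.failures) and not self.reports


def analyze_chain(structure: Structure, chain_id: str, config: AnalysisConfig) -> dict:
    """Quartets, core, ions, topology and orientations for one chain.

    Returns a JSON-ready dict; raises when the chain holds no stacked core.
    """
    chain = Structure(model_id=structure.model_id,
                      chains={chain_id: list(structure.chain(chain_id))})
    quartets = detect_quartets(chain, config.hbond_max, config.planarity_max)
    core = build_core(quartets, config.stack_window)
    ions = assign_ions(core, structure, config.radial_max)
    topo = classify_topology(core, chain)
    core_keys = core.core_keys()
    seqidx = sequential_index(chain.nucleotides(chain_id))

    orientations = {}
    extra = [r for r in chain.nucleotides(chain_id) if r.key not in core_keys]
    for res in extra:
        call = classify_base_orientation(
            res, core,
            stack_candidates=extra,
            stack_lateral_max=config.stack_lateral_max,
            stack_axial_window=config.stack_axial_window,
            elevation_cut=config.elevation_cut,
            plane_angle_max=config.plane_angle_max,
        )
        orientations[f"{res.label}"] = {
            "category": call.category,
            "stack_partner": call.stack_partner.label if call.stack_partner else None,
            "axial": call.axial_component,
            "radial": call.radial_component,
            "elevation_deg": call.elevation_angle,
        }

    clefts = []
    inverse = {pos: key for key, pos in seqidx.items()}
    for pa, pb in config.cleft_pairs:
        if pa in inverse and pb in inverse:
            ra = chain.residue(*inverse[pa])
            rb = chain.residue(*inverse[pb])
            if ra.atom("P") is not None and rb.atom("P") is not None:
                m = cleft_width(chain, ra, rb)
                clefts.append({"pair": m.label, "distance_A": round(m.distance, 1)})

    return {
        "chain": chain_id,
        "n_layers": core.n_layers,
        "rise_per_layer_A": list(core.rise_per_layer),
        "axis": list(core.axis),
        "quartets": [
            {
                "members": [g.label for g in q.guanines],
                "planarity_rms_A": q.planarity_rms,
            }
            for q in core.layers
        ],
        "channel_ions": [
            {"ion": r.label, "inter_layer_gap": gap} for r, gap in ions.channel_ions
        ],
        "external_ions": [
            {"ion": r.label, "nearest": near} for r, near in ions.external_ions
        ],
        "topology": {
            "tracts": [list(t) for t in topo.tracts],
            "loops": [
                {"residues": list(l.labels), "type": l.loop_type} for l in topo.loops
            ],
            "strand_senses": topo.strand_senses,
            "snapback": topo.snapback_labels,
        },
        "orientations": orientations,
        "clefts": clefts,
    }


def _quadruplex_chains(structure: Structure) -> list[str]:
    from .structures import base_code

    out = []
    for cid, residues in structure.chains.items():
        n_g = sum(1 for r in residues if base_code(r.name) == "G")
        if n_g >= 8:  # at least two quartet layers' worth of guanines
            out.append(cid)
    return out


def _analyze_one(path: Path, config: AnalysisConfig, out_dir: Path) -> list[str]:
    ensemble = read_structures(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    first = ensemble[0]
    chains = _quadruplex_chains(first)
    if not chains:
        raise ValueError(f"{path.name}: no chain with >= 8 guanines")

    chain_reports = {}
    for cid in chains:
        chain_reports[cid] = analyze_chain(first, cid, config)
    _write_json({"input": path.name, "chains": chain_reports}, out_dir / "topology.json")
    written.append("topology.json")

    # torsion table: one column per chain, all nucleotide positions
    n_pos = min(len(first.nucleotides(cid)) for cid in chains)
    labeled = [
        (cid, Structure(model_id=first.model_id, chains={cid: list(first.chain(cid))}))
        for cid in chains
    ]
    table = torsion_table(labeled, residues=list(range(1, n_pos + 1)))
    table.round(1).to_csv(out_dir / "torsions.csv")
    written.append("torsions.csv")

    _write_json(
        {cid: chain_reports[cid]["orientations"] for cid in chains},
        out_dir / "orientation.json",
    )
    written.append("orientation.json")

    flex_rows = []
    for cid in chains:
        profile = normalize_profile(
            residue_bfactors(first, config.atom_scope, cid), config.normalization
        )
        frame = profile.as_frame()
        frame.insert(0, "chain", cid)
        flex_rows.append(frame)
    import pandas as pd

    pd.concat(flex_rows).to_csv(out_dir / "flexibility.csv", index=False)
    written.append("flexibility.csv")

    if len(ensemble) >= 2:
        core = build_core(
            detect_quartets(first, config.hbond_max, config.planarity_max),
            config.stack_window,
        )
        rmsf = normalize_profile(
            ensemble_rmsf(ensemble, core_guanine_selection(core)), config.normalization
        )
        rmsf.as_frame().to_csv(out_dir / "rmsf.csv", index=False)
        written.append("rmsf.csv")

    if len(ensemble) >= 4:
        dm = distance_matrix(ensemble)
        k = select_k(dm, k_max=min(config.k_max, len(ensemble) - 1), seed=config.seed)
        model = cluster_medoids(dm, k, seed=config.seed)
        graph = transition_graph(model, dm.frame_labels)
        _write_json(
            {
                "k": model.k,
                "nodes": [
                    {
                        "id": cid,
                        "population": model.populations[cid],
                        "medoid_frame": model.medoid_indices[cid],
                    }
                    for cid in range(model.k)
                ],
                "edges": [
                    {"from": i, "to": j, "count": int(graph.counts[i, j])}
                    for i in range(model.k)
                    for j in range(model.k)
                    if i != j and graph.counts[i, j]
                ],
            },
            out_dir / "clusters.json",
        )
        written.append("clusters.json")
    return written


def analyze(
    inputs: list[str | Path],
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "quadgeom_out",
) -> AnalysisResult:
    """Run the full analysis over coordinate files; one subdirectory each.

    Failures are recorded per input; the run only counts as failed when
    every input fails.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    result = AnalysisResult(out_dir=out_dir)
    for item in inputs:
        path = Path(item)
        target = out_dir / path.stem
        try:
            result.reports[path.name] = _analyze_one(path, config, target)
        except Exception as exc:  # noqa: BLE001 - per-input isolation is the contract
            log.error("%s failed: %s", path.name, exc)
            result.failures[path.name] = str(exc)
    manifest = {
        "version": _version,
        "config": config.to_dict(),
        "config_hash": config.hash,
        "inputs": sorted(r for r in result.reports),
        "failures": result.failures,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_json(manifest, out_dir / "manifest.json")
    return result
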