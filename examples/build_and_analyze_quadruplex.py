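"""Build an idealized parallel quadruplex and read its fold back off the
geometry alone.

The generator plants a three-layer parallel fold (30 degrees twist, 3.3 A
rise, three single-nucleotide loops swung outward, K+ ions in the channel);
the analysis side rediscovers quartets from Hoogsteen hydrogen-bond cycles,
stacks them into a core, assigns the ions and classifies the topology —
with no access to the generator's bookkeeping.
"""

from quadgeom.quartets import assign_ions, build_core, classify_topology, detect_quartets
from quadgeom.synthetic import QuadruplexSpec, build_quadruplex

spec = QuadruplexSpec()  # 3 layers, twist 30 deg, rise 3.3 A, loops "out"
structure = build_quadruplex(spec)
print(f"built: {len(structure.nucleotides('A'))} nucleotides "
      f"(+{sum(r.is_hetero for r in structure.residues())} channel ions)")

quartets = detect_quartets(structure)
print(f"\nquartets detected: {len(quartets)}")
for q in quartets:
    members = ",".join(g.label for g in q.guanines)
    print(f"  [{members}]  planarity rms {q.planarity_rms:.4f} A")

core = build_core(quartets)
rises = ", ".join(f"{r:.3f}" for r in core.rise_per_layer)
print(f"\ncore: {core.n_layers} layers, rise per layer = {rises} A")
print("  (the planted 3.3 A rise is recovered exactly)")

ions = assign_ions(core, structure)
for ion, gap in ions.channel_ions:
    print(f"channel ion {ion.label} between layers {gap} and {gap + 1}")

report = classify_topology(core, structure)
print(f"\ntopology: tracts {report.tracts}")
for loop in report.loops:
    print(f"  loop {'-'.join(loop.labels)}: {loop.loop_type}")
print(f"strand senses: {report.strand_senses}")
print("\nAll three loops classify propeller and all four columns run "
      "parallel - the signature of a promoter-type parallel fold.")
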