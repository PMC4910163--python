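"""Train a myristoylation site predictor on planted data and predict sites.

Generates 30 synthetic substrate proteins whose N-terminal glycines follow
the MGXXXS/T consensus, runs the full training pipeline (grouping, motif
length selection, ALC-PSO weight training and matrix mutation), and predicts
sites back on the same sequences at medium stringency. Printed: the selected
scoring window, the groups, and the first few predicted sites with their
scores — a site is reported when its score reaches the group cutoff
calibrated to 90% specificity.
"""

from lipidsites import synth, training

proteins, sites = synth.generate(
    synth.SynthSpec(mod_type="MYR", n_positive=30, signal_strength=0.9, seed=2)
)
model = training.train(
    proteins, sites, "MYR", training.TrainConfig(seed=3, pso_iterations=50)
)
print(f"selected window: ({model.m},{model.n})")
for g in model.groups:
    print(f"group {g.group_id}: {len(g.positives)} peptides, "
          f"medium cutoff {g.thresholds['medium']:.2f}")

hits = training.predict(model, proteins, stringency="medium")
truth = {(s.protein_id, s.position) for s in sites}
recovered = sum(1 for h in hits if (h.protein_id, h.position) in truth)
print(f"\n{len(hits)} predictions at medium stringency; "
      f"{recovered}/{len(truth)} annotated sites recovered")
for h in hits[:5]:
    print(f"  {h.protein_id} pos {h.position:>3} {h.peptide} "
          f"score {h.score:6.2f} (cutoff {h.cutoff:.2f}, {h.group_id})")
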