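"""Evaluate a trained palmitoylation model by LOO and 4-fold cross-validation.

Palmitoylation has no consensus motif, so positives are clustered (k = 3)
before scoring. The script prints the LOO and 4-fold AUC — the probability
that a random true site outscores a random non-site — and the thresholded
metrics (Sn, Sp, Ac, MCC, Pr) at the medium-stringency cutoff.
"""

from lipidsites import evaluation, synth, training

proteins, sites = synth.generate(
    synth.SynthSpec(mod_type="PALM", n_positive=60, signal_strength=0.8, seed=1)
)
model = training.train(
    proteins, sites, "PALM", training.TrainConfig(seed=1, pso_iterations=100)
)
ts = training.build_training_set(proteins, sites, "PALM")

loo = evaluation.loo_scores(model, ts)
_, loo_auc = evaluation.roc_auc(loo)
kf = evaluation.kfold_scores(model, ts, k=4, seed=0)
_, kf_auc = evaluation.roc_auc(kf)
print(f"LOO AUC:    {loo_auc:.4f}  ({ts.residue}-candidates: "
      f"{len(ts.positives)} pos / {len(ts.negatives)} neg)")
print(f"4-fold AUC: {kf_auc:.4f}  (fast mode: global weights, per-fold peptide sets)")

cuts = evaluation.calibrate_thresholds(loo)
ms = evaluation.metrics(evaluation.confusion_at(loo, cuts["medium"]))
print(f"at medium stringency (Sp target 0.90): "
      f"Sn={ms.sn:.3f} Sp={ms.sp:.3f} Ac={ms.ac:.3f} MCC={ms.mcc:.3f} Pr={ms.pr:.3f}")
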