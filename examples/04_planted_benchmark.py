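"""Train the full pipeline on a planted drug-target interaction dataset.

Generates a low-rank interaction structure (drugs and targets with latent
vectors; the top 15% of noisy inner products are the positive pairs), trains
the projection heads, fusion gates, two-layer mean-aggregation GNN and pair
MLP end-to-end on a 70/10/20 random split, and reports held-out metrics
averaged over two seeded runs.  Smaller than the benchmark in the test suite
so it finishes in seconds.
"""

from topolink import ExperimentConfig, ModelConfig, NodeInputs, run_experiment
from topolink.synthetic import PlantedDTISpec, gen_dti_dataset

spec = PlantedDTISpec(n_drugs=80, n_targets=60, latent_dim=4, density=0.1,
                      noise_sd=0.1, seed=5)
ds = gen_dti_dataset(spec)
print(f"dataset: {spec.n_drugs} drugs x {spec.n_targets} targets, "
      f"{(ds.pairs.label == 1).sum()} positives, "
      f"{(ds.pairs.label == 0).sum()} negatives")


def inputs_for(drug_ids, target_ids):
    return NodeInputs.from_tables(drug_ids, target_ids, ds.drug_llm,
                                  ds.drug_topo, ds.target_llm, ds.target_topo)


report = run_experiment(ExperimentConfig(
    pairs=ds.pairs, inputs_for=inputs_for, seeds=(0, 1),
    model=ModelConfig(max_epochs=60)))

print(f"\nheld-out metrics, mean +/- sd over {report.n_runs} runs:")
for metric in ("auroc", "auprc", "sensitivity", "specificity"):
    print(f"  {metric:12s} {report.mean[metric]:.3f} +/- {report.sd[metric]:.3f}")
print("\nAUROC well above 0.5 shows the model recovers the planted latent "
      "structure from the signal-bearing sequence embeddings.")
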