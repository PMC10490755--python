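"""Train the deformation network on tiny synthetic shells and reconstruct.

A miniature version of the full study (small grid, few shells, two epochs)
that runs in about a minute on a laptop CPU; the package-scale experiment
is `myomesh.pipeline.run_desk_study`.
"""

from myomesh.pipeline import (
    ReconstructionModel, TrainConfig, evaluate_model, prepare_case, train,
)
from myomesh.synthetic_data import make_dataset

manifest = make_dataset(
    n_base=6, n_augment=6, splits=(5, 1), n_test=1, seed=11,
    grid_size=44, scale=(44 - 6) / 96.0,
)
config = TrainConfig.desk_scale(seed=11, epochs=4, hidden=16, width_scale=0.2,
                                n_eval_samples=4000, n_loss_samples=1500)
model = ReconstructionModel(config)
bundles = {
    split: [prepare_case(c, model, i) for i, c in enumerate(manifest.realize(split))]
    for split in ("train", "val", "test")
}

result = train(config, manifest, bundles=bundles)
for row in result.history:
    print(f"epoch {row['epoch']}: train loss {row['mean_loss']:.5f}, "
          f"validation Chamfer {row['val_chamfer']:.5f}")

_, mean = evaluate_model(result.model, bundles["test"])
print(f"\nheld-out shell: initial Chamfer {mean['initial_chamfer']:.5f} "
      f"-> deformed {mean['final_chamfer']:.5f}")
print(f"normal consistency: {mean['initial_normal']:.3f} -> {mean['final_normal']:.3f}")
# The deformed mesh should sit closer to the smooth label surface than the
# staircase it started from; at this miniature scale the margin is small.
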