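"""Full pipeline at miniature scale: generate, train, evaluate.

Uses a 3-class ladder, 32 px renders and the 0.25-width network so the whole
run finishes in about a minute on one CPU.  The acceptance script and test
suite run the same pipeline at the larger desk scale (5 classes, 64 px).
"""

import tempfile

from platevol import ReferenceScheme, SimulatorParams, evaluate, generate_dataset, mean_rve
from platevol.nn.network import NetworkConfig, build_network
from platevol.nn.train import TrainingPolicy, train

scheme = ReferenceScheme(n_classes=3, v_min=200, v_max=1100)

with tempfile.TemporaryDirectory() as workdir:
    manifest = generate_dataset(
        scheme, n_train_per_class=30, n_test_per_class=15,
        sim_params=SimulatorParams(out_size=32, n_theta=48, n_phi=24),
        seed=7, out_dir=workdir,
    )
    model = build_network(NetworkConfig(n_classes=3, input_size=32, width_multiplier=0.25, seed=7))
    policy = TrainingPolicy(batch_size=16, total_steps=250, seed=7)
    log = train(model, manifest, scheme, policy, images_dir=workdir)
    print(f"trained {log.step.iloc[-1]} steps; "
          f"loss {log.loss.iloc[0]:.3f} -> {log.loss.iloc[-1]:.3f}")

    report = evaluate(model, manifest, scheme, images_dir=workdir)

o = report.overall()
centre = (scheme.v_min + scheme.v_max) / 2
baseline = mean_rve([(centre, v) for v in report.true_volumes])
print(f"test top1 {100*o['top1']:.1f}%   top3 {100*o['top3']:.1f}%")
print(f"mRVE soft {100*o['mrve_soft']:.1f}%   hard {100*o['mrve_hard']:.1f}%   "
      f"always-guess-centre {100*baseline:.1f}%")
print(report.to_table().to_string())

# top3 counts predictions within one class of the truth; mRVE is the mean of
# |V_pred - V_true| / V_true over the test split.  Soft decoding should sit
# below both the hard baseline and the centre-guess baseline.
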