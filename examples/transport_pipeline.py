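"""Motion-state analysis of a synthetic axonal-transport cohort.

Generates a control cohort from the three-state preset (diffusive +
anterograde + retrograde), runs the full pipeline — quality filter, pooled
Bayesian model selection, per-trajectory refits, Viterbi annotation — and
prints the recovered state speeds and pooled transition probabilities next
to the generating values.  A smaller cohort than the validation default is
used so the example runs in well under a minute.
"""

from dataclasses import replace

from uspt import synthdata as sd
from uspt import transport as tr

preset = replace(sd.make_control_preset(), n_trajectories=20)
trajs, truth = sd.generate_cohort(preset, seed=3)
kept, rejected = tr.filter_trajectories(trajs)
print(f"{len(kept)}/{len(trajs)} trajectories pass the length/SNR filter")

analysis = tr.analyze_cohort(kept, seed=4)
sel = analysis.pooled_selection
print("\npooled model probabilities:")
for spec, p in sorted(sel.probabilities.items(), key=lambda kv: -kv[1])[:4]:
    print(f"  {','.join(spec):9s} {p:.4f}")
print(f"selected: {','.join(analysis.spec)}")

summary = tr.aggregate_statistics(analysis,
                                  localization_sigma_nm=preset.localization_sigma)
targets = truth.groupby("label")["target_speed"].mean()
print("\nrecovered state speeds (um/s) vs generating cohort means:")
for label, s in summary.state_summaries.items():
    print(f"  {label:12s} {s.mean_speed:.3f}  (truth {targets[label]:.3f}, "
          f"occupancy {s.occupancy_fraction:.2f})")

print("\npooled transition probabilities (rows: from-state):")
print(summary.transition_matrix.round(3).to_string())
print("-> the diffusion->retrograde entry is the rarest move: retrograde "
      "runs are reached via anterograde transport.")
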