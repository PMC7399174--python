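"""Score model predictions against a dose-matrix viability screen.

The screen is binarized by mean HSA excess (combination viability minus
the best single agent, averaged over the dose grid; <= -0.11 calls a
synergy).  Predictions are summarised as a confusion matrix with the
standard panel of metrics, next to the expectation under random guessing
(100,000 seeded draws of the same number of predicted pairs).
"""

import synlogic as sl

bundle = sl.make_bundle(seed=1, noise_sd=0.02)

observed = sl.score_screen(list(bundle.screen_records))
print(f"screen: {observed.n_pairs} pairs, {observed.n_synergies} observed "
      f"synergies at cutoff {observed.cutoff}")
worked = bundle.screen_records[0]
res = sl.hsa_excess(worked)
print(f"\nHSA excess grid for {worked.pair} (rows: dose A, cols: dose B):")
print(res.excess.round(3).to_string())
print(f"mean excess {res.mean:.3f} -> "
      f"{'synergistic' if res.mean <= observed.cutoff else 'not synergistic'}")

cal = sl.calibrate(bundle.generic_model,
                   sl.combine_profiles(bundle.profile_literature,
                                       bundle.profile_omics))
calls = sl.predict_synergies(cal.model, bundle.panel,
                             reference_state=cal.selected_state)
summary = sl.confusion(calls.predictions(), observed)
print("\nmodel predictions vs screen:", summary.report())

baseline = sl.random_baseline(calls.n_predicted, observed, reps=100_000, seed=0)
print(f"random baseline ({baseline.reps} draws of {baseline.n_predicted} pairs): "
      f"expected TP {baseline.expected_tp:.1f} "
      f"(closed form {baseline.analytic_tp:.2f}) vs model TP {summary.tp}")
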