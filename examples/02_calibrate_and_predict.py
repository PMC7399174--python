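"""Calibrate a generic model to a cell line and predict drug-pair synergies.

Uses a synthetic study with planted ground truth: the generic model's
link operators are calibrated against the baseline activity profile
(literature overlaid on omics), then every single and double drug
perturbation is simulated and pairs whose viability falls strictly below
both single drugs are called synergistic.
"""

import synlogic as sl

bundle = sl.make_bundle(seed=1)
profile = sl.combine_profiles(bundle.profile_literature, bundle.profile_omics)
print(f"cell line {profile.cell_line}: {profile.n_non_na} baseline activities "
      f"({bundle.profile_literature.n_non_na} literature, rest omics-inferred)")

cal = sl.calibrate(bundle.generic_model, profile)
print(f"calibration: {len(cal.changes)} link-operator flip(s) "
      f"{[e.args['node'] for e in cal.changes]}, "
      f"agreement {cal.matched_fraction:.0%} (planted flips: {list(bundle.planted_flips)})")

calls = sl.predict_synergies(cal.model, bundle.panel,
                             reference_state=cal.selected_state,
                             cell_line=profile.cell_line)
print(f"\n{len(calls.pairs)} drug pairs from {len(bundle.panel.drugs)} inhibitors:")
print(sl.calls_to_frame(calls).to_string(index=False))
predicted = sorted(p for p, c in calls.pairs.items() if c.predicted)
print(f"\npredicted synergies: {predicted}")
print(f"planted synergies:   {sorted(bundle.planted_synergies)}")
print("a pair is called synergistic when viability_ab < min(viability_a, viability_b)")
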