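"""From a signed interaction network to a logical model and its stable states.

Builds a small signaling cascade in the 3-column text dialect, derives
the generic rules (activators OR-ed, inhibitors dominating via AND NOT),
applies the OR NOT exception that keeps a stress kinase active when all
of its regulators are silent, and enumerates the fixed points.
"""

import synlogic as sl

NETWORK = """\
GF\tactivate\tRTK
RTK\tactivate\tMAP2K3
RTK\tactivate\tMAP2K4
MAP2K3\tactivate\tMAPK14
MAP2K4\tactivate\tMAPK14
DUSP1\tinhibit\tMAPK14
MAPK14\tactivate\tProsurvival
RTK\tactivate\tProsurvival
DUSP1\tactivate\tAntisurvival
"""

net = sl.parse_network(NETWORK, output_nodes=("Prosurvival", "Antisurvival"),
                       drug_target_nodes={"RTK"})
report = sl.validate_network(net)
print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges; "
      f"connectivity clean: {report.connectivity_clean}")

model = sl.default_rules(net, link_overrides={"MAPK14": sl.OR_NOT})
print("\nrules (node, expression, max level):")
print(sl.write_rules(model))

# GF and DUSP1 are inputs: each 0/1 combination admits one fixed point
states = sl.stable_states(model)
print(f"{len(states)} stable states; with growth factor on and phosphatase off:")
chosen = [s for s in states if s["GF"] == 1 and s["DUSP1"] == 0][0]
print({n: v for n, v in chosen.items()})
print("viability (prosurvival - antisurvival):",
      chosen["Prosurvival"] - chosen["Antisurvival"])

# reduction keeps the druggable receptor and the outputs, eliminating the rest
reduced = sl.reduce_model(model, {"RTK", "GF", "DUSP1", "Prosurvival", "Antisurvival"})
print("\nreduced model keeps:", ", ".join(reduced.nodes))
print("projected fixed points preserved:",
      sl.project_states(states, reduced.nodes)
      == sl.project_states(sl.stable_states(reduced), reduced.nodes))
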