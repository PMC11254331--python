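"""Round-trip a trial extract through the custom upload schema.

The custom format is what a user would prepare for their own trial: a
CSV with a patient-identifier column, a time-point column and one
response column (the column header names the symptom), plus an explicit
declared ordering of time points and responses. Nothing is inferred from
the file; the mapping config is the contract.
"""

from pathlib import Path

import toxflow as tf

OUT = Path("scratch/examples")
OUT.mkdir(parents=True, exist_ok=True)

# a three-arm chemotherapy-style PRO trial, one symptom
table = tf.simulate_trial(tf.preset("b30-pro"), n_per_arm=60,
                          term="numbness", seed=11)

csv_path = OUT / "upload.csv"
mapping = tf.write_custom_table(table, csv_path)
tf.save_mapping(mapping, table.scale.missing_level, OUT / "mapping.json")
print(f"wrote {csv_path} with columns "
      f"{mapping.id_column}/{mapping.time_column}/{mapping.response_column}")

again = tf.read_custom_table(csv_path, mapping, table.scale.missing_level,
                             scale=table.scale)
print("read back identical to the original:", again == table)

traj = tf.pivot_trajectories(again, "numbness", "AT")
graph = tf.build_flow_graph(traj)
fig = tf.render_sankey(graph, traj.scale, "numbness — AT",
                       OUT / "sankey_custom.svg", "svg")
print(f"rendered {fig} over stages {graph.stages[0]} → {graph.stages[-1]}")
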