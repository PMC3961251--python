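"""Evaluate biclusters produced by an external tool via the exchange format.

Any biclustering program's output can be benchmarked by writing it as the
versioned JSON exchange document ({schema_version, method_name, parameters,
biclusters: [{genes, samples}, ...]}).  Here one is constructed in-process:
a deliberately imperfect result that merges two tissues into one bicluster.
"""

import bicbench as bb

cfg = bb.desk_config(seed=3)
matrix, labels, truth = bb.generate_multitissue_dataset(cfg)
tiger, _ = bb.generate_annotation_sets(truth, cfg)

t1, t2 = labels.types[0], labels.types[1]
merged = bb.Bicluster(
    truth.type_signatures[t1] | truth.type_signatures[t2],
    labels.samples_of_type(t1) | labels.samples_of_type(t2),
)
external = bb.BiclusterSet("some_external_tool", {"setting": 7}, [merged])
bb.save_bicluster_set(external, "examples_output_external.json")
loaded = bb.load_bicluster_set("examples_output_external.json")

sd = bb.sample_dif(loaded, labels)
n1 = len(labels.samples_of_type(t1))
n2 = len(labels.samples_of_type(t2))
print(f"imported '{loaded.method_name}': k = {loaded.k}")
print(f"SampleDif = {sd:.4f}")
print(f"expected: best Dice match is with the larger type "
      f"2*{max(n1,n2)}/({max(n1,n2)}+{n1+n2}) = "
      f"{2*max(n1,n2)/(max(n1,n2)+n1+n2):.4f}")
print("merging two tissues is penalized: the bicluster can match only one "
      "of them\nin the greedy assignment, at a diluted overlap.")
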