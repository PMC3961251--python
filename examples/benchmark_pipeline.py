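"""Full pipeline: simulate -> preprocess -> methods -> filter -> benchmark.

Compares one-way clustering of samples (k-means, hierarchical) against the
perfect-recovery oracle on a simulated five-tissue dataset, writing every
intermediate artifact under examples_output/ and printing the report table
(one row per method: SampleDif, TiGER-Sig, GO-Sig, gene-overlap bias).
"""

import bicbench as bb

cfg = bb.PipelineConfig(
    output_dir="examples_output/pipeline_run",
    simulation=bb.SimulationConfig(
        n_genes=600,
        type_sizes={"blood_tcell": 15, "cerebral_cortex": 24, "liver": 3,
                    "striated_muscle": 10, "testis": 5},
        signature_size=40,
        effect_size=2.0,
        seed=5,
    ),
    methods=[
        {"name": "oracle"},
        {"name": "kmeans", "axis": "samples", "k": 5, "seed": 5},
        {"name": "hierarchical", "axis": "samples", "k": 5},
    ],
    benchmark=bb.BenchmarkConfig(alpha=0.05, n_resamples=500, seed=5),
)

report = bb.run_pipeline(cfg)
cols = ["method", "k", "sample_dif", "tiger_sig", "go_sig", "mean_gene_overlap"]
print("\t".join(cols))
for row in report.rows:
    print("\t".join(
        f"{row[c]:.3f}" if isinstance(row[c], float) else str(row[c])
        for c in cols))
print("\nSampleDif = 1 means each tissue is matched exactly by a distinct "
      "bicluster; one-way\nclustering of samples scores below the oracle "
      "because clusters must span all genes\nand tissue boundaries blur "
      "in full-transcriptome distances.  The gene-based\ncolumns are 0 for "
      "sample partitions (their 'gene set' is the whole universe, which\n"
      "can never be enriched), and mean_gene_overlap = 1 flags exactly that "
      "degeneracy.")
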