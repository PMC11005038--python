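"""Structure-independence assessment: three CV regimes side by side.

Runs the full pipeline (LLMs -> activity matrix -> QIVIVE -> rule) on a
synthetic dataset and evaluates the PK metamodel under repeated random
CV, similarity-cluster CV (folds are structural clusters) and ATC-group
CV (folds are therapeutic classes), then prints the similarity
diagnostics that justify the cluster split.
"""

import tempfile

import numpy as np

from cholepk.evaluation import similarity_report
from cholepk.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    synthetic={"n_compounds": 250, "seed": 12},
    seed=12,
    out_dir=tempfile.mkdtemp(prefix="cholepk_example_"),
    llm_families=("SVM",),
    cv_schemes=("repeated_random", "similarity_cluster", "atc_group"),
    cv_repeats=5)
art = run_pipeline(cfg)

print(f"tuned safety factor n = {art['metamodel_pk'].n_factor_:.2f}\n")
print(f"{'scheme':20s} {'S':>6s} {'SP':>6s} {'A':>6s} {'MCC':>6s}")
for kind, rep in art["reports"].items():
    print(f"{kind:20s} {rep.mean('S'):6.3f} {rep.mean('SP'):6.3f} "
          f"{rep.mean('A'):6.3f} {rep.mean('MCC'):6.3f}")

ds = art["dataset"]
idx = {c: i for i, c in enumerate(ds.compound_ids)}
rows = [idx[c] for c in art["dose_matrix"].compound_ids]
sim = similarity_report(ds.fingerprints[rows], ds.clusters[rows], k=3)
mat = sim.matrix.to_numpy(dtype=float)
print(f"\nintra-cluster top-3 Tanimoto mean: {np.diag(mat).mean():.3f}")
print(f"inter-cluster top-3 Tanimoto mean: "
      f"{mat[~np.eye(len(mat), dtype=bool)].mean():.3f}")
# Because the labels are generated by the dose rule (not by chemical
# series), the metamodel's performance barely moves when the test folds
# become structurally dissimilar from training - the property the
# similarity and ATC regimes are designed to probe.
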