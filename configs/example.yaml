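# Full-pipeline run configuration. Flags on `neurofeat run` override keys.
scope: subject_independent   # or subject_dependent
feature_sets: [ND, FD]       # any of TD, FD, TF, ND, TD+FD+TF, TD+FD+TF+ND
alpha: 0.05
k: 5
seed: 1
n_subjects: 2                # study design default is 8
n_per_class: 20              # study design default is 100
effect: per_class            # null | planted | per_class
effect_multiplier: 4.0
families: [svm, knn]         # omit for all eight families
variants: [linear, cosine]   # omit for all catalogued variants
out: runs/example
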