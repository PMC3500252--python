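"""Balanced cross-validated evaluation of the RBF-SVM predictor.

Runs the full protocol at reduced scale: positives paired with two
balanced negative sets, 5-fold stratified CV, KNN reference and SVM
training restricted to each training fold.  Prints Acc/Sn/Sp/MCC as
mean ± sd over the negative-set repetitions.
"""

from acetylsite import (
    SvmConfig,
    SyntheticDatasetSpec,
    compute_ig_profile,
    cross_validate,
    generate_fragments,
    sample_balanced_negative_sets,
    select_positions,
)

corpus, _ = generate_fragments(
    SyntheticDatasetSpec(n_positive=400, n_negative=1200, seed=2)
)
positives = corpus.subset("positive")
negatives = corpus.subset("negative")

balanced = positives + negatives[: len(positives)]
profile = compute_ig_profile(balanced, [f.label for f in balanced])
mask = select_positions(profile, 13)
print(f"IG-selected mask: {list(mask.offsets)}")

neg_sets = sample_balanced_negative_sets(negatives, len(positives), n_sets=2, seed=2)
result = cross_validate(
    positives, neg_sets, mask,
    svm_config=SvmConfig(c_grid=(1.0,), gamma_grid=(1.0 / 278,)),
    folds=5, seed=2,
)
print(result.format_summary())
# Sensitivity is the fraction of acetylated sites recovered, specificity
# the fraction of non-acetylated lysines correctly rejected; MCC balances
# all four confusion counts and is the headline comparison metric.
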