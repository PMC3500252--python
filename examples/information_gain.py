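"""Rank window offsets by information gain and pick a position mask.

Generates a corpus whose positives carry lysine enrichment at offsets
−8..−1 and arginine at +1, computes per-offset IG, and selects the 9
most informative offsets — which should recover the planted set.
"""

from acetylsite import (
    SyntheticDatasetSpec,
    compute_ig_profile,
    generate_fragments,
    positionwise_enrichment,
    select_positions,
)

corpus, truth = generate_fragments(
    SyntheticDatasetSpec(n_positive=2000, n_negative=2000, seed=0)
)
profile = compute_ig_profile(list(corpus), corpus.labels)

print(f"class entropy H(X) = {profile.class_entropy_bits:.3f} bits")
print("offset  IG (bits)")
for off in profile.offsets:
    bar = "#" * int(200 * profile.ig_bits[off])
    print(f"{off:+3d}     {profile.ig_bits[off]:.4f}  {bar}")

mask = select_positions(profile, 9)
print(f"\nselected 9-offset mask: {list(mask.offsets)}")
print(f"planted informative offsets: {truth['informative_offsets']}")

calls = positionwise_enrichment(list(corpus), corpus.labels, alpha=1e-4)
flagged = calls[calls["call"] != ""]
print(f"\n{len(flagged)} (offset, residue) cells flagged at p ≤ 1e-4; "
      f"e.g. {flagged.iloc[0]['residue']} at {flagged.iloc[0]['offset']:+d} "
      f"is {flagged.iloc[0]['call']} "
      f"({flagged.iloc[0]['freq_positive']:.2f} vs {flagged.iloc[0]['freq_negative']:.2f})")
# High IG marks offsets whose residue distribution differs between
# acetylated and non-acetylated fragments; the mask keeps only those.
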