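"""Build a fragment corpus from annotated protein sequences.

Generates a small synthetic proteome with known acetylation sites,
writes it as FASTA + TSV, reads it back through the corpus readers,
extracts 21-mer lysine-centered windows, removes redundant fragments
and enumerates candidate negative sites.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from acetylsite import (
    SyntheticDatasetSpec,
    build_corpus,
    enumerate_negative_sites,
    generate_annotated_proteins,
    read_fasta,
    read_site_annotations,
    reduce_redundancy,
)

spec = SyntheticDatasetSpec(n_positive=100, n_negative=100, seed=0)
fasta_text, tsv_text, _ = generate_annotated_proteins(spec)

with TemporaryDirectory() as d:
    fasta = Path(d) / "proteome.fasta"
    sites = Path(d) / "sites.tsv"
    fasta.write_text(fasta_text)
    sites.write_text(tsv_text)

    proteins = read_fasta(fasta)
    annotations = read_site_annotations(sites, proteins)

positives = [a for a in annotations if a.label == "positive"]
corpus = build_corpus(proteins, positives)
kept = reduce_redundancy(list(corpus), threshold=0.30)
negatives = enumerate_negative_sites(proteins, positives)

print(f"proteins:            {len(proteins)}")
print(f"annotated positives: {len(positives)}")
print(f"fragments kept after 30% redundancy filter: {len(kept)}")
print(f"candidate negative lysines (unannotated K): {len(negatives)}")
print(f"example fragment ({kept[0].protein_id}:{kept[0].center_position}): "
      f"{kept[0].residues}")
# The fragment string is the ±10-residue window around the lysine; the
# negative count exceeds the positive count because most lysines in a
# proteome are not acetylated.
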