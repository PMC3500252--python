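"""Fragment corpus construction.

Reads protein sequences (FASTA) and acetylation-site annotations (TSV),
extracts lysine-centered windows with terminal padding, enumerates
candidate negative sites, removes redundant fragments, samples balanced
negative training sets, and splits proteins into training and holdout
partitions.

Coordinates are 1-based in annotation files; internally every window
position is addressed by a signed offset (negative = upstream/N-terminal,
0 = the candidate lysine).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, PAD, validate_sequence

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet (uppercase; 'X' tolerated)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        validate_sequence(self.sequence, allow_pad=True)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate acetylation site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class WindowSpec:
    """A lysine-centered window: ``upstream`` residues before the site and
    ``downstream`` after it, padded with ``pad_symbol`` past either terminus.

    The default (10, 10) yields the 21-mer window used throughout.
    """

    upstream: int = 10
    downstream: int = 10
    pad_symbol: str = PAD

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window arms must be non-negative")
        if len(self.pad_symbol) != 1 or self.pad_symbol in AMINO_ACIDS:
            raise ValueError("pad symbol must be a single non-amino-acid character")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream + 1

    @property
    def offsets(self) -> range:
        """Signed offsets −upstream..+downstream inclusive."""
        return range(-self.upstream, self.downstream + 1)


@dataclass(frozen=True)
class SiteFragment:
    """A fixed-length residue window centered on a lysine, with a class label."""

    protein_id: str
    center_position: int
    residues: str
    label: str
    window: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if len(self.residues) != self.window.length:
            raise ValueError(
                f"fragment length {len(self.residues)} != window length {self.window.length}"
            )
        if self.residues[self.window.upstream] != "K":
            raise ValueError("residue at offset 0 must be 'K'")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.center_position)

    def residue_at(self, offset: int) -> str:
        """Residue at a signed offset (0 = the central lysine)."""
        return self.residues[offset + self.window.upstream]


@dataclass
class FragmentCorpus:
    """An ordered collection of fragments sharing one window spec."""

    fragments: list[SiteFragment]
    window: WindowSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for f in self.fragments:
            if f.window != self.window:
                raise ValueError("all fragments must share the corpus window spec")
            if f.key in seen:
                raise ValueError(f"duplicate fragment key {f.key}")
            seen.add(f.key)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.fragments]

    def subset(self, label: str) -> list[SiteFragment]:
        return [f for f in self.fragments if f.label == label]


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated, uppercased protein records.

    Duplicate identifiers and characters outside the alphabet (plus 'X')
    are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ValueError(f"FASTA entry {rec.id!r}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_site_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read a site-annotation TSV (``protein_id<TAB>position[<TAB>label]``, with header).

    Each annotation is validated against the protein sequences: the position
    must be in range and the residue there must be a lysine.
    """
    by_id = {p.id: p for p in proteins}
    annotations: list[SiteAnnotation] = []
    errors: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "protein_id":
            raise ValueError("annotation file must start with a 'protein_id' header column")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                errors.append(f"row {lineno}: expected at least 2 columns")
                continue
            pid, pos_s = parts[0], parts[1]
            label = parts[2] if len(parts) > 2 and parts[2] else POSITIVE
            if pid not in by_id:
                errors.append(f"row {lineno}: unknown protein id {pid!r}")
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                errors.append(f"row {lineno}: non-integer position {pos_s!r}")
                continue
            seq = by_id[pid].sequence
            if not 1 <= pos <= len(seq):
                errors.append(f"row {lineno}: position {pos} out of range for {pid!r}")
                continue
            if seq[pos - 1] != "K":
                errors.append(
                    f"row {lineno}: residue at {pid}:{pos} is {seq[pos - 1]!r}, not 'K'"
                )
                continue
            annotations.append(SiteAnnotation(protein_id=pid, position=pos, label=label))
    if errors:
        raise ValueError("invalid site annotations:\n" + "\n".join(errors))
    keys = [(a.protein_id, a.position) for a in annotations]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (protein_id, position) annotation rows")
    return annotations


def write_corpus_tsv(corpus: FragmentCorpus, path: str | Path) -> None:
    """Write fragments as ``protein_id<TAB>position<TAB>label<TAB>fragment`` TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\tfragment\n")
        for f in corpus:
            fh.write(f"{f.protein_id}\t{f.center_position}\t{f.label}\t{f.residues}\n")


def read_corpus_tsv(path: str | Path, window: WindowSpec | None = None) -> FragmentCorpus:
    """Read a fragment-corpus TSV written by :func:`write_corpus_tsv`."""
    fragments: list[SiteFragment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "position", "label", "fragment"]:
            raise ValueError("unexpected corpus TSV header")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, label, frag = line.rstrip("\n").split("\t")[:4]
            if window is None:
                if len(frag) % 2 == 0:
                    raise ValueError("cannot infer window from even-length fragment")
                arm = (len(frag) - 1) // 2
                window = WindowSpec(arm, arm)
            fragments.append(
                SiteFragment(pid, int(pos), frag, label, window=window)
            )
    if window is None:
        raise ValueError(f"no fragments found in {path}")
    return FragmentCorpus(fragments, window, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Window extraction and negative enumeration


def extract_fragment(
    protein: ProteinRecord,
    position: int,
    window: WindowSpec = WindowSpec(),
    label: str = POSITIVE,
) -> SiteFragment:
    """Extract the window centered on a 1-based lysine position, padding past termini."""
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} out of range for {protein.id!r}")
    if seq[position - 1] != "K":
        raise ValueError(
            f"center residue at {protein.id}:{position} is {seq[position - 1]!r}, not 'K'"
        )
    chars = []
    for off in window.offsets:
        i = position - 1 + off
        chars.append(seq[i] if 0 <= i < len(seq) else window.pad_symbol)
    return SiteFragment(protein.id, position, "".join(chars), label, window=window)


def enumerate_negative_sites(
    proteins: Sequence[ProteinRecord],
    positive_annotations: Sequence[SiteAnnotation],
) -> list[SiteAnnotation]:
    """Every lysine position not annotated positive, labeled negative."""
    positives = {(a.protein_id, a.position) for a in positive_annotations}
    negatives: list[SiteAnnotation] = []
    for p in proteins:
        for i, ch in enumerate(p.sequence, start=1):
            if ch == "K" and (p.id, i) not in positives:
                negatives.append(SiteAnnotation(p.id, i, NEGATIVE))
    return negatives


def build_corpus(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    window: WindowSpec = WindowSpec(),
    provenance: dict | None = None,
) -> FragmentCorpus:
    """Extract one fragment per annotation into a corpus."""
    by_id = {p.id: p for p in proteins}
    fragments = [
        extract_fragment(by_id[a.protein_id], a.position, window, label=a.label)
        for a in annotations
    ]
    return FragmentCorpus(fragments, window, provenance=dict(provenance or {}))


# ---------------------------------------------------------------------------
# Redundancy reduction


def fragment_identity(a: SiteFragment, b: SiteFragment) -> float:
    """Fraction of window offsets carrying the identical residue (pad matches pad)."""
    if a.window.length != b.window.length:
        raise ValueError("fragments have different window lengths")
    same = sum(x == y for x, y in zip(a.residues, b.residues))
    return same / a.window.length


def reduce_redundancy(
    fragments: Iterable[SiteFragment], threshold: float = 0.30
) -> list[SiteFragment]:
    """Greedy keep-first redundancy scan.

    Fragments are scanned in (protein_id, center_position) order; a fragment
    is discarded iff its identity with an already-retained fragment strictly
    exceeds ``threshold``.  Vectorized over integer residue codes.
    """
    ordered = sorted(fragments, key=lambda f: f.key)
    if not ordered:
        return []
    length = ordered[0].window.length
    mat = np.frombuffer(
        "".join(f.residues for f in ordered).encode("ascii"), dtype=np.uint8
    ).reshape(len(ordered), length)
    retained_rows: list[np.ndarray] = []
    retained: list[SiteFragment] = []
    for frag, row in zip(ordered, mat):
        if retained_rows:
            kept = np.vstack(retained_rows)
            identity = (kept == row).mean(axis=1)
            if float(identity.max()) > threshold:
                continue
        retained_rows.append(row)
        retained.append(frag)
    return retained


# ---------------------------------------------------------------------------
# Balanced negative sampling and protein-level holdout


def sample_balanced_negative_sets(
    negatives: Sequence[SiteFragment],
    n_positive: int,
    n_sets: int = 5,
    seed: int = 0,
) -> list[list[SiteFragment]]:
    """Draw ``n_sets`` independent balanced negative subsets of size ``n_positive``.

    Each subset is drawn without replacement; subsets may overlap across
    draws.  Reproducible under ``seed``.
    """
    if n_positive > len(negatives):
        raise ValueError(
            f"cannot draw {n_positive} negatives from a pool of {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    pool = sorted(negatives, key=lambda f: f.key)
    sets = []
    for _ in range(n_sets):
        idx = rng.choice(len(pool), size=n_positive, replace=False)
        sets.append([pool[i] for i in sorted(idx)])
    return sets


def hold_out_proteins(
    proteins: Sequence[ProteinRecord], fraction: float = 0.10, seed: int = 0
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Protein-level split: no protein contributes fragments to both sides."""
    if not 0 < fraction < 1:
        raise ValueError("holdout fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    ordered = sorted(proteins, key=lambda p: p.id)
    n_holdout = int(round(fraction * len(ordered)))
    idx = set(rng.choice(len(ordered), size=n_holdout, replace=False).tolist())
    holdout = [p for i, p in enumerate(ordered) if i in idx]
    training = [p for i, p in enumerate(ordered) if i not in idx]
    return training, holdout
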