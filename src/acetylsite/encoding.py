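"""Feature encoders: one-hot residues, KNN similarity scores, and
physicochemical property values.

Three blocks make up the feature vector of a masked fragment with L
encoded positions:

* **BE** — one-hot ("binary") encoding, a 20-slot block per position in
  the fixed alphabet order, 20·L values; the pad symbol encodes as all
  zeros.
* **KNN** — five nearest-neighbor scores: for each of five neighborhood
  sizes K (fractions of the reference-set size), the fraction of
  positive-labeled fragments among the K nearest reference fragments
  under a substitution-matrix distance.
* **AASA** — the per-residue value of an amino-acid property index
  (default: average accessible surface area), one value per position,
  min-max scaled so the 20 index values span [0, 1]; pad encodes as 0.

The fragment distance is ``D(S1, S2) = 1 − (1/L)·Σ_i Sim(S1[i], S2[i])``
where ``Sim`` is BLOSUM62 min-max normalized to [0, 1] globally and any
pairing involving the pad symbol has similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .aaindex import PropertyIndex, janin_asa_index
from .alphabet import AMINO_ACIDS, PAD_CODE, encode_residues
from .corpus import POSITIVE, SiteFragment

# ---------------------------------------------------------------------------
# Substitution similarity


@dataclass(frozen=True)
class SubstitutionSimilarity:
    """A 20×20 substitution matrix min-max normalized to [0, 1].

    ``sim_padded`` is the 21×21 working matrix whose last row/column is the
    pad symbol with similarity 0 against everything (including itself).
    """

    name: str
    raw: np.ndarray          # 20×20 integer-valued scores, alphabet order
    sim: np.ndarray          # 20×20 in [0, 1]
    sim_padded: np.ndarray   # 21×21, pad row/col zero

    def similarity(self, a: str, b: str) -> float:
        codes = encode_residues(a + b)
        return float(self.sim_padded[codes[0], codes[1]])


def normalize_substitution_matrix(
    matrix: np.ndarray, name: str = "custom"
) -> SubstitutionSimilarity:
    """Build a :class:`SubstitutionSimilarity` from a raw 20×20 matrix.

    ``Sim = (M − min M) / (max M − min M)``; the input must be symmetric
    and indexed in the standard alphabet order.
    """
    M = np.asarray(matrix, dtype=float)
    if M.shape != (20, 20):
        raise ValueError(f"expected a 20×20 matrix, got {M.shape}")
    if not np.array_equal(M, M.T):
        raise ValueError("substitution matrix must be symmetric")
    lo, hi = M.min(), M.max()
    if hi == lo:
        raise ValueError("degenerate substitution matrix (constant scores)")
    sim = (M - lo) / (hi - lo)
    padded = np.zeros((21, 21))
    padded[:20, :20] = sim
    return SubstitutionSimilarity(name=name, raw=M, sim=sim, sim_padded=padded)


def blosum62_similarity() -> SubstitutionSimilarity:
    """BLOSUM62 normalized to [0, 1] (min −4 → 0, max 11 → 1)."""
    bl = substitution_matrices.load("BLOSUM62")
    M = np.array([[bl[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS])
    return normalize_substitution_matrix(M, name="BLOSUM62")


# ---------------------------------------------------------------------------
# Block encoders


def binary_encode(residues: str) -> np.ndarray:
    """One-hot encode a residue string: 20 slots per position, pad → all zeros."""
    codes = encode_residues(residues)
    out = np.zeros(20 * len(codes))
    for i, c in enumerate(codes):
        if c != PAD_CODE:
            out[20 * i + c] = 1.0
    return out


def property_encode(
    residues: str, index: PropertyIndex | None = None, scaling: str = "minmax"
) -> np.ndarray:
    """Encode each position by its property-index value; pad → 0.

    With ``scaling="minmax"`` (default) the 20 index values are affinely
    rescaled to span [0, 1] before lookup; ``scaling="none"`` keeps raw
    magnitudes.
    """
    index = index if index is not None else janin_asa_index()
    table = _property_table(index, scaling)
    codes = encode_residues(residues)
    return table[codes]


def _property_table(index: PropertyIndex, scaling: str) -> np.ndarray:
    vals = np.array([index.values[aa] for aa in AMINO_ACIDS])
    if scaling == "minmax":
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            vals = (vals - lo) / (hi - lo)
        else:
            vals = np.zeros_like(vals)
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    return np.append(vals, 0.0)  # pad slot


# ---------------------------------------------------------------------------
# Distances and KNN scores


def fragment_distance(s1: str, s2: str, sim: SubstitutionSimilarity) -> float:
    """``1 − mean positional similarity``; symmetric, in [0, 1]."""
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    c1, c2 = encode_residues(s1), encode_residues(s2)
    return 1.0 - float(sim.sim_padded[c1, c2].mean())


def code_matrix(fragments: Sequence[SiteFragment] | Sequence[str]) -> np.ndarray:
    """Integer residue codes, one row per fragment (pad = 20)."""
    rows = [
        encode_residues(f.residues if isinstance(f, SiteFragment) else f)
        for f in fragments
    ]
    return np.asarray(rows, dtype=np.int8)


def distance_matrix(
    a_codes: np.ndarray, b_codes: np.ndarray, sim: SubstitutionSimilarity
) -> np.ndarray:
    """Pairwise fragment distances between two code matrices (rows × rows)."""
    if a_codes.shape[1] != b_codes.shape[1]:
        raise ValueError("code matrices must share the window length")
    L = a_codes.shape[1]
    total = np.zeros((a_codes.shape[0], b_codes.shape[0]))
    for p in range(L):
        total += sim.sim_padded[a_codes[:, p][:, None], b_codes[:, p][None, :]]
    return 1.0 - total / L


@dataclass(frozen=True)
class KnnConfig:
    """Neighborhood sizes for the KNN block, as fractions of the reference size.

    The defaults (0.025%, 0.05%, 0.1%, 0.2%, 0.4%) span increasingly coarse
    views of the local similarity neighborhood.  ``k = max(minimum_k,
    round-half-up(fraction × N))``.
    """

    k_fractions: tuple[float, ...] = (0.00025, 0.0005, 0.001, 0.002, 0.004)
    minimum_k: int = 1

    def __post_init__(self) -> None:
        fr = self.k_fractions
        if not fr or any(not 0 < f < 1 for f in fr) or list(fr) != sorted(set(fr)):
            raise ValueError("k_fractions must be strictly increasing fractions in (0,1)")

    def ks(self, n_reference: int) -> list[int]:
        return [
            max(self.minimum_k, int(np.floor(f * n_reference + 0.5)))
            for f in self.k_fractions
        ]


def knn_score(
    query: SiteFragment,
    reference: Sequence[SiteFragment],
    k: int,
    sim: SubstitutionSimilarity | None = None,
) -> float:
    """Fraction of positive fragments among the k nearest reference fragments.

    Reference fragments sharing the query's (protein_id, center_position)
    are excluded (self-exclusion); ties in distance break by reference
    (protein_id, position) order so scores are bit-reproducible.
    """
    sim = sim if sim is not None else blosum62_similarity()
    ordered = sorted(reference, key=lambda f: f.key)
    ordered = [f for f in ordered if f.key != query.key]
    if k > len(ordered):
        raise ValueError(f"k={k} exceeds usable reference size {len(ordered)}")
    d = distance_matrix(code_matrix([query]), code_matrix(ordered), sim)[0]
    nearest = np.argsort(d, kind="stable")[:k]
    return sum(ordered[i].label == POSITIVE for i in nearest) / k


def knn_feature_vector(
    query: SiteFragment,
    reference: Sequence[SiteFragment],
    config: KnnConfig = KnnConfig(),
    sim: SubstitutionSimilarity | None = None,
) -> np.ndarray:
    """The five KNN scores for one query, in config fraction order."""
    sim = sim if sim is not None else blosum62_similarity()
    n_usable = sum(f.key != query.key for f in reference)
    return np.array(
        [knn_score(query, reference, k, sim) for k in config.ks(n_usable)]
    )


def knn_score_matrix(
    queries: Sequence[SiteFragment],
    reference: Sequence[SiteFragment],
    config: KnnConfig,
    sim: SubstitutionSimilarity,
) -> np.ndarray:
    """Vectorized KNN block: one row of five scores per query.

    Semantics match :func:`knn_score` (self-exclusion by fragment key,
    stable distance ties by reference key order).  K values are computed
    from the self-excluded reference size, which on a corpus containing
    the queries themselves is the same for every query.
    """
    ordered = sorted(reference, key=lambda f: f.key)
    ref_codes = code_matrix(ordered)
    ref_pos = np.array([f.label == POSITIVE for f in ordered], dtype=float)
    key_index = {}
    for i, f in enumerate(ordered):
        key_index.setdefault(f.key, []).append(i)

    D = distance_matrix(code_matrix(queries), ref_codes, sim)
    n_usable = None
    for qi, q in enumerate(queries):
        excluded = key_index.get(q.key, [])
        if excluded:
            D[qi, excluded] = np.inf
        usable = len(ordered) - len(excluded)
        n_usable = usable if n_usable is None else min(n_usable, usable)

    ks = config.ks(n_usable)
    if ks[-1] > n_usable:
        raise ValueError(f"k={ks[-1]} exceeds usable reference size {n_usable}")
    order = np.argsort(D, axis=1, kind="stable")
    pos_sorted = ref_pos[order[:, : ks[-1]]]
    cum = np.cumsum(pos_sorted, axis=1)
    return np.column_stack([cum[:, k - 1] / k for k in ks])


# ---------------------------------------------------------------------------
# Assembled feature vectors


BLOCK_NAMES = ("BE", "KNN", "AASA")


@dataclass(frozen=True)
class FeatureLayout:
    """Named spans of the assembled feature vector, with per-column names."""

    blocks: tuple[tuple[str, int, int], ...]  # (name, start, stop)
    column_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.column_names)

    def span(self, block: str) -> slice:
        for name, start, stop in self.blocks:
            if name == block:
                return slice(start, stop)
        raise KeyError(f"no block {block!r} in layout")


def build_layout(
    offsets: Sequence[int],
    blocks: Sequence[str] = BLOCK_NAMES,
    config: KnnConfig = KnnConfig(),
) -> FeatureLayout:
    """Layout for the chosen blocks over the encoded offsets."""
    _check_blocks(blocks)
    spans, names = [], []
    cursor = 0
    for block in blocks:
        if block == "BE":
            cols = [f"BE[{off:+d}][{aa}]" for off in offsets for aa in AMINO_ACIDS]
        elif block == "KNN":
            cols = [f"KNN[{100 * f:g}%]" for f in config.k_fractions]
        else:
            cols = [f"AASA[{off:+d}]" for off in offsets]
        spans.append((block, cursor, cursor + len(cols)))
        names.extend(cols)
        cursor += len(cols)
    return FeatureLayout(blocks=tuple(spans), column_names=tuple(names))


def _check_blocks(blocks: Sequence[str]) -> None:
    if not blocks:
        raise ValueError("at least one feature block required")
    bad = [b for b in blocks if b not in BLOCK_NAMES]
    if bad:
        raise ValueError(f"unknown feature blocks {bad}; choose from {BLOCK_NAMES}")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: FeatureLayout


class FeatureEncoder:
    """Encodes masked fragments into [BE | KNN | AASA] feature matrices.

    Parameters
    ----------
    offsets
        The signed window offsets to encode (a position mask's offsets).
    blocks
        Subset of ``("BE", "KNN", "AASA")`` to include, in that order.
    sim, index, knn_config
        Substitution similarity, property index and KNN neighborhood
        schedule; defaults are normalized BLOSUM62, the Janin
        accessible-surface-area index (min-max scaled) and the standard
        five fractions.

    The KNN block always measures distance over the *masked* residues, and
    its reference set is supplied per call so cross-validation can restrict
    it to the training fold.
    """

    def __init__(
        self,
        offsets: Sequence[int],
        blocks: Sequence[str] = BLOCK_NAMES,
        sim: SubstitutionSimilarity | None = None,
        index: PropertyIndex | None = None,
        knn_config: KnnConfig = KnnConfig(),
        property_scaling: str = "minmax",
    ) -> None:
        _check_blocks(blocks)
        self.offsets = tuple(offsets)
        self.blocks = tuple(blocks)
        self.sim = sim if sim is not None else blosum62_similarity()
        self.index = index if index is not None else janin_asa_index()
        self.knn_config = knn_config
        self.property_scaling = property_scaling
        self.layout = build_layout(self.offsets, self.blocks, knn_config)
        self._prop_table = _property_table(self.index, property_scaling)

    def masked_residues(self, fragment: SiteFragment) -> str:
        return "".join(fragment.residue_at(off) for off in self.offsets)

    def _masked(self, fragments: Sequence[SiteFragment]) -> list[SiteFragment]:
        # Re-wrap masked strings as lightweight fragments so KNN keeps keys.
        masked = []
        for f in fragments:
            obj = object.__new__(SiteFragment)
            object.__setattr__(obj, "protein_id", f.protein_id)
            object.__setattr__(obj, "center_position", f.center_position)
            object.__setattr__(obj, "residues", self.masked_residues(f))
            object.__setattr__(obj, "label", f.label)
            object.__setattr__(obj, "window", f.window)
            masked.append(obj)
        return masked

    def encode_matrix(
        self,
        fragments: Sequence[SiteFragment],
        reference: Sequence[SiteFragment] | None = None,
    ) -> np.ndarray:
        """Feature matrix (len(fragments) × layout.n_features).

        ``reference`` is required whenever the KNN block is included.
        """
        parts = []
        codes = code_matrix([self.masked_residues(f) for f in fragments])
        for block in self.blocks:
            if block == "BE":
                onehot = np.zeros((len(fragments), 20 * len(self.offsets)))
                for p in range(len(self.offsets)):
                    col = codes[:, p].astype(np.intp)
                    live = col != PAD_CODE
                    onehot[np.where(live)[0], 20 * p + col[live]] = 1.0
                parts.append(onehot)
            elif block == "KNN":
                if reference is None:
                    raise ValueError("KNN block requires a reference fragment set")
                parts.append(
                    knn_score_matrix(
                        self._masked(fragments),
                        self._masked(reference),
                        self.knn_config,
                        self.sim,
                    )
                )
            else:
                parts.append(self._prop_table[codes])
        return np.hstack(parts)

    def encode(
        self,
        fragment: SiteFragment,
        reference: Sequence[SiteFragment] | None = None,
    ) -> FeatureVector:
        values = self.encode_matrix([fragment], reference)[0]
        return FeatureVector(values=values, layout=self.layout)


def assemble_features(
    fragment: SiteFragment,
    offsets: Sequence[int],
    reference: Sequence[SiteFragment] | None = None,
    sim: SubstitutionSimilarity | None = None,
    index: PropertyIndex | None = None,
    config: KnnConfig = KnnConfig(),
    blocks: Sequence[str] = BLOCK_NAMES,
) -> FeatureVector:
    """One-shot [BE | KNN | AASA] vector for a single fragment."""
    enc = FeatureEncoder(offsets, blocks, sim=sim, index=index, knn_config=config)
    return enc.encode(fragment, reference)


def features_to_frame(X: np.ndarray, layout: FeatureLayout) -> pd.DataFrame:
    """Feature matrix as a DataFrame with block/offset column names (CSV-ready)."""
    return pd.DataFrame(X, columns=list(layout.column_names))


def screen_property_indices(
    indices: Sequence[PropertyIndex],
    fragments: Sequence[SiteFragment],
    labels: Sequence[str],
    offsets: Sequence[int] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank property indices by cross-validated accuracy of a property-only model.

    Each index is evaluated alone (AASA-style positional encoding, no BE or
    KNN block) with a default-parameter RBF SVM, mirroring how candidate
    physicochemical indices are screened before one is adopted.  Returns a
    DataFrame (index_name, cv_accuracy) sorted by accuracy descending, ties
    broken by name.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    if not indices:
        raise ValueError("no property indices supplied")
    names = [ix.name for ix in indices]
    if len(set(names)) != len(names):
        raise ValueError("duplicate property index names")
    if offsets is None:
        window = fragments[0].window
        offsets = [o for o in window.offsets if o != 0]
    y = np.array([lab == POSITIVE for lab in labels], dtype=int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for ix in indices:
        enc = FeatureEncoder(offsets, blocks=("AASA",), index=ix)
        X = enc.encode_matrix(list(fragments))
        acc = cross_val_score(SVC(), X, y, cv=cv, scoring="accuracy").mean()
        rows.append({"index_name": ix.name, "cv_accuracy": float(acc)})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["cv_accuracy", "index_name"], ascending=[False, True]
    ).reset_index(drop=True)
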