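"""Position analysis: per-offset information gain, position masks, and
composition/enrichment statistics.

The informativeness of each window offset is measured by information
gain: ``IG(c) = H(X) − H_c(X|Y)``, where X is the class variable
(acetylated / non-acetylated), Y the residue observed at offset c, H the
Shannon entropy in bits, and probabilities are maximum-likelihood counts
over the corpus.  The pad symbol counts as a 21st observable value of Y,
since truncated windows near protein termini are themselves informative
about position.  Offsets with the largest IG form the position mask
("IG window") used for encoding; preset masks of sizes 9-17 are bundled,
as are contiguous symmetric "general" windows for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .alphabet import AMINO_ACIDS, PAD
from .corpus import NEGATIVE, POSITIVE, SiteFragment

# ---------------------------------------------------------------------------
# Entropy and information gain


def class_entropy(labels: Sequence[str]) -> float:
    """Shannon entropy of the class labels, in bits (0·log 0 ≡ 0)."""
    if len(labels) == 0:
        raise ValueError("no labels")
    n_pos = sum(lab == POSITIVE for lab in labels)
    probs = np.array([n_pos, len(labels) - n_pos]) / len(labels)
    return float(-sum(p * math.log2(p) for p in probs if p > 0))


def _contingency(
    fragments: Sequence[SiteFragment], labels: Sequence[str], offset: int
) -> dict[str, tuple[int, int]]:
    """symbol → (count among positives, count among negatives) at an offset."""
    table: dict[str, list[int]] = {}
    for frag, lab in zip(fragments, labels):
        sym = frag.residue_at(offset)
        cell = table.setdefault(sym, [0, 0])
        cell[0 if lab == POSITIVE else 1] += 1
    return {s: (c[0], c[1]) for s, c in table.items()}


def conditional_entropy(
    fragments: Sequence[SiteFragment],
    labels: Sequence[str],
    offset: int,
    pseudocount: float = 0.0,
) -> float:
    """H(X|Y) at one offset, in bits: Σ_y P(y)·H(class | Y=y).

    ``pseudocount`` adds a Laplace prior over the full 21-symbol × 2-class
    table (useful for very small corpora); the default is unsmoothed
    maximum likelihood.
    """
    table = _contingency(fragments, labels, offset)
    if pseudocount > 0:
        for sym in AMINO_ACIDS + PAD:
            n_pos, n_neg = table.get(sym, (0, 0))
            table[sym] = (n_pos + pseudocount, n_neg + pseudocount)
    n = sum(n_pos + n_neg for n_pos, n_neg in table.values())
    h = 0.0
    for n_pos, n_neg in table.values():
        n_y = n_pos + n_neg
        for c in (n_pos, n_neg):
            if c > 0:
                h -= (n_y / n) * (c / n_y) * math.log2(c / n_y)
    return h


@dataclass(frozen=True)
class IGProfile:
    """Per-offset information gain with the entropy terms behind it."""

    offsets: tuple[int, ...]
    class_entropy_bits: float
    conditional_entropy_bits: dict[int, float]
    ig_bits: dict[int, float]
    counts: dict[int, dict[str, tuple[int, int]]]  # offset → symbol → (pos, neg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": list(self.offsets),
                "ig_bits": [self.ig_bits[o] for o in self.offsets],
                "conditional_entropy_bits": [
                    self.conditional_entropy_bits[o] for o in self.offsets
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame()[["offset", "ig_bits"]].to_csv(path, sep="\t", index=False)


def compute_ig_profile(
    fragments: Sequence[SiteFragment],
    labels: Sequence[str],
    pseudocount: float = 0.0,
) -> IGProfile:
    """Information gain at every window offset.

    Offset 0 is the invariant central lysine and is reported with IG 0.
    Requires both classes to be present.  ``pseudocount`` enables Laplace
    smoothing of the conditional entropies for tiny corpora.
    """
    label_set = set(labels)
    if not {POSITIVE, NEGATIVE} <= label_set:
        raise ValueError("information gain requires both classes present")
    window = fragments[0].window
    hx = class_entropy(labels)
    cond: dict[int, float] = {}
    ig: dict[int, float] = {}
    counts: dict[int, dict[str, tuple[int, int]]] = {}
    for off in window.offsets:
        if off == 0:
            cond[off] = hx
            ig[off] = 0.0
            counts[off] = _contingency(fragments, labels, off)
            continue
        h = conditional_entropy(fragments, labels, off, pseudocount=pseudocount)
        cond[off] = h
        ig[off] = hx - h
        counts[off] = _contingency(fragments, labels, off)
    return IGProfile(
        offsets=tuple(window.offsets),
        class_entropy_bits=hx,
        conditional_entropy_bits=cond,
        ig_bits=ig,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Position masks


@dataclass(frozen=True)
class PositionMask:
    """An ordered set of signed offsets selecting informative positions.

    Masks never contain offset 0: the central lysine is constant within a
    lysine-centered corpus and is excluded from the encoded positions.
    """

    offsets: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        offs = self.offsets
        if list(offs) != sorted(set(offs)):
            raise ValueError("mask offsets must be strictly increasing and unique")
        if 0 in offs:
            raise ValueError("mask must not contain offset 0 (the central lysine)")

    def __len__(self) -> int:
        return len(self.offsets)

    def to_json(self) -> str:
        return json.dumps({self.name: list(self.offsets)})


def select_positions(profile: IGProfile, size: int) -> PositionMask:
    """The ``size`` offsets with largest IG.

    Ties break toward smaller |offset|, then upstream (negative) first.
    Offset 0 is never selectable.
    """
    candidates = [o for o in profile.offsets if o != 0]
    if not 1 <= size <= len(candidates):
        raise ValueError(f"mask size {size} out of range 1..{len(candidates)}")
    ranked = sorted(
        candidates, key=lambda o: (-profile.ig_bits[o], abs(o), o > 0)
    )
    chosen = sorted(ranked[:size])
    return PositionMask(offsets=tuple(chosen), name=f"computed-ig:{size}")


_IG_PRESETS: dict[str, tuple[int, ...]] = {
    "IG9": (-8, -7, -6, -5, -4, -3, -2, -1, +1),
    "IG11": (-8, -7, -6, -5, -4, -3, -2, -1, +1, +4, +6),
    "IG13": (-8, -7, -6, -5, -4, -3, -2, -1, +1, +3, +4, +6, +7),
    "IG15": (-8, -7, -6, -5, -4, -3, -2, -1, +1, +3, +4, +5, +6, +7, +9),
    "IG17": (-8, -7, -6, -5, -4, -3, -2, -1, +1, +2, +3, +4, +5, +6, +7, +8, +9),
}


def preset_mask(name: str) -> PositionMask:
    """A named preset: ``IG{9,11,13,15,17}`` (position-specific masks derived
    from the IG ranking on the acetylation corpus) or ``general{9,11,...,21}``
    (contiguous symmetric windows ``−(W−1)/2..+(W−1)/2`` minus the center)."""
    if name in _IG_PRESETS:
        return PositionMask(offsets=_IG_PRESETS[name], name=name)
    if name.startswith("general"):
        try:
            w = int(name[len("general"):])
        except ValueError:
            w = -1
        if w in range(9, 22, 2):
            arm = (w - 1) // 2
            offs = tuple(o for o in range(-arm, arm + 1) if o != 0)
            return PositionMask(offsets=offs, name=name)
    valid = sorted(_IG_PRESETS) + [f"general{w}" for w in range(9, 22, 2)]
    raise ValueError(f"unknown mask {name!r}; valid names: {', '.join(valid)}")


def full_window_mask(window) -> PositionMask:
    """Every non-center offset of a window spec."""
    return PositionMask(
        offsets=tuple(o for o in window.offsets if o != 0), name="full"
    )


def apply_mask(fragment: SiteFragment, mask: PositionMask) -> str:
    """Residues at the masked offsets in ascending order (center excluded)."""
    w = fragment.window
    for off in mask.offsets:
        if not -w.upstream <= off <= w.downstream:
            raise ValueError(f"mask offset {off:+d} outside window −{w.upstream}..+{w.downstream}")
    return "".join(fragment.residue_at(off) for off in mask.offsets)


# ---------------------------------------------------------------------------
# Composition and per-position enrichment


def composition_frequencies(
    fragments_by_class: Mapping[str, Sequence[SiteFragment]]
) -> pd.DataFrame:
    """Per-class amino-acid frequencies over all non-pad window positions.

    Returns a DataFrame indexed by amino acid with one column per class;
    each column sums to 1 (pads excluded from denominators).
    """
    cols = {}
    for cls, fragments in fragments_by_class.items():
        if not fragments:
            raise ValueError(f"empty class {cls!r}")
        counts = {aa: 0 for aa in AMINO_ACIDS}
        total = 0
        for f in fragments:
            for ch in f.residues:
                if ch != PAD:
                    counts[ch] += 1
                    total += 1
        cols[cls] = {aa: counts[aa] / total for aa in AMINO_ACIDS}
    return pd.DataFrame(cols)


def positionwise_enrichment(
    fragments: Sequence[SiteFragment],
    labels: Sequence[str],
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Per (offset, residue) enrichment/depletion of positives vs negatives.

    For every offset and amino acid, a two-proportion z-test compares the
    occurrence frequency in the positive class against the negative class.
    A cell is flagged ``enriched`` (``depleted``) when p ≤ alpha and the
    positive frequency is higher (lower).  No multiple-testing correction
    is applied — the fixed stringent alpha plays that role — but the number
    of tests performed is recorded in ``frame.attrs["n_tests"]``.
    """
    pos = [f for f, lab in zip(fragments, labels) if lab == POSITIVE]
    neg = [f for f, lab in zip(fragments, labels) if lab == NEGATIVE]
    if not pos or not neg:
        raise ValueError("both classes required")
    window = fragments[0].window
    rows = []
    n_tests = 0
    for off in window.offsets:
        if off == 0:
            continue
        pos_syms = [f.residue_at(off) for f in pos]
        neg_syms = [f.residue_at(off) for f in neg]
        for aa in AMINO_ACIDS:
            k_pos = sum(s == aa for s in pos_syms)
            k_neg = sum(s == aa for s in neg_syms)
            if k_pos + k_neg == 0:
                continue
            n_tests += 1
            if k_pos + k_neg == len(pos) + len(neg) or k_pos + k_neg == 0:
                p_value = 1.0
                stat = 0.0
            else:
                stat, p_value = proportions_ztest(
                    [k_pos, k_neg], [len(pos), len(neg)]
                )
            f_pos, f_neg = k_pos / len(pos), k_neg / len(neg)
            call = ""
            if alpha > 0 and p_value <= alpha:
                call = "enriched" if f_pos > f_neg else "depleted"
            rows.append(
                {
                    "offset": off,
                    "residue": aa,
                    "freq_positive": f_pos,
                    "freq_negative": f_neg,
                    "z": float(stat),
                    "p_value": float(p_value),
                    "call": call,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["n_tests"] = n_tests
    frame.attrs["alpha"] = alpha
    return frame
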