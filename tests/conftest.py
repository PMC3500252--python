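import numpy as np
import pytest

from acetylsite import (
    MotifSpec,
    SiteFragment,
    SyntheticDatasetSpec,
    WindowSpec,
    blosum62_similarity,
    generate_fragments,
    janin_asa_index,
)


@pytest.fixture(scope="session")
def sim():
    return blosum62_similarity()


@pytest.fixture(scope="session")
def janin():
    return janin_asa_index()


def make_fragment(residues, pid="p1", pos=None, label="positive"):
    """A fragment whose window is inferred from the (odd) residue length."""
    arm = (len(residues) - 1) // 2
    window = WindowSpec(arm, arm)
    return SiteFragment(pid, pos if pos is not None else arm + 1, residues, label, window=window)


def random_fragments(n, rng, window=WindowSpec(2, 2), p_positive=0.5, prefix="r"):
    """Uniform-background fragments with random labels, unique keys."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    fragments = []
    for i in range(n):
        chars = [alphabet[c] for c in rng.integers(0, 20, size=window.length)]
        chars[window.upstream] = "K"
        label = "positive" if rng.random() < p_positive else "negative"
        fragments.append(
            SiteFragment(f"{prefix}{i:04d}", window.upstream + 1, "".join(chars), label, window=window)
        )
    return fragments


@pytest.fixture(scope="session")
def planted_corpus():
    """A small corpus with the calibration motif (seed fixed)."""
    spec = SyntheticDatasetSpec(n_positive=300, n_negative=300, seed=11)
    corpus, truth = generate_fragments(spec)
    return corpus, truth
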