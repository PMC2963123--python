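import numpy as np
import pytest

from phylopair.align import AMINO_ACIDS


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs distinct positions with a different residue."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def caterpillar_newick(names: list[str], branch: float = 1.0) -> str:
    """Fully pectinate (caterpillar) tree over names."""
    core = f"({names[0]}:{branch},{names[1]}:{branch})"
    for name in names[2:-1]:
        core = f"({core}:{branch},{name}:{branch})"
    return f"({core}:{branch},{names[-1]}:{branch});"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
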