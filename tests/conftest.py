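import numpy as np
import pytest

from orthotraits.tree import Phylogeny, parse_newick


@pytest.fixture
def write_file(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return parse_newick("((A:1,B:1):1,C:2);")


def star_tree(n: int, length: float = 1.0) -> Phylogeny:
    """Star phylogeny: n tips hanging directly off the root."""
    parent = [-1] + [0] * n
    lengths = [0.0] + [length] * n
    labels = [None] + [f"t{i + 1}" for i in range(n)]
    return Phylogeny(parent, lengths, labels)


def random_tree(n_tips: int, seed: int, height: float = 1.0) -> Phylogeny:
    """Random ultrametric tree via the package's own coalescence generator."""
    from orthotraits.simulate import SynthSpec, gen_tree

    return gen_tree(SynthSpec(seed=seed, n_tips=n_tips, tree_height=height))
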