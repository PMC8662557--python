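from pathlib import Path

import numpy as np
import pytest

from taxconcord.io import read_gold_standard, read_qiime2_taxonomy, read_rdp_fixrank
from taxconcord.taxonomy import Lineage, build_lineage

DATA = Path(__file__).parent / "data"

# a small pool of plausible lineage components for random-lineage generation
_HIGH = ["Fungi", "Basidiomycota", "Ascomycota", "Agaricomycetes", "Sordariomycetes"]
_ORDERS = ["Agaricales", "Hymenochaetales", "Mucorales", "Hypocreales"]
_FAMILIES = ["Psathyrellaceae", "Schizoporaceae", "Mucoraceae", "Nectriaceae"]
_GENERA = ["Coprinopsis", "Xylodon", "Mucor", "Fusarium", "Phellinus"]
_EPITHETS = ["cinerea", "subflaviporus", "circinelloides", "oxysporum", "igniarius"]


def random_lineage(rng: np.random.Generator, depth: int | None = None) -> Lineage:
    """A random lineage truncated at a random depth (0 = empty)."""
    if depth is None:
        depth = int(rng.integers(0, 7))
    genus = _GENERA[rng.integers(len(_GENERA))]
    pairs = [
        ("kingdom", _HIGH[0]),
        ("phylum", _HIGH[rng.integers(1, 3)]),
        ("class", _HIGH[rng.integers(3, 5)]),
        ("order", _ORDERS[rng.integers(len(_ORDERS))]),
        ("family", _FAMILIES[rng.integers(len(_FAMILIES))]),
        ("genus", genus),
        ("species", f"{genus} {_EPITHETS[rng.integers(len(_EPITHETS))]}"),
    ]
    return build_lineage(pairs[:depth])


@pytest.fixture(scope="session")
def five_otu_tables():
    """The five-OTU worked example, read through the real dialect readers."""
    return {
        "qiime": read_qiime2_taxonomy(DATA / "qiime_five_otu.tsv"),
        "rdp": read_rdp_fixrank(DATA / "rdp_five_otu.tsv"),
        "gold": read_gold_standard(DATA / "gold_five_otu.tsv"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
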