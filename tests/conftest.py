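"""Shared fixtures: toy libraries and planted landscapes, built once per session."""

import numpy as np
import pytest

from evoscreen import chemlib, fixtures


@pytest.fixture(scope="session")
def tiny_spec() -> fixtures.ToyLibrarySpec:
    """One two-component reaction with slots of 3 and 4 → 12 products."""
    return fixtures.ToyLibrarySpec(
        reactions=(fixtures.ReactionSpec(arity=2, slot_sizes=(3, 4)),), seed=7
    )


@pytest.fixture(scope="session")
def tiny_library(tiny_spec, tmp_path_factory) -> chemlib.CombinatorialLibrary:
    out = tmp_path_factory.mktemp("tiny-lib")
    return fixtures.load_toy_library(tiny_spec, out)


@pytest.fixture(scope="session")
def mixed_spec() -> fixtures.ToyLibrarySpec:
    """A 3×4 two-component reaction plus a 2×2×2 three-component one → 20 products."""
    return fixtures.ToyLibrarySpec(
        reactions=(
            fixtures.ReactionSpec(arity=2, slot_sizes=(3, 4)),
            fixtures.ReactionSpec(arity=3, slot_sizes=(2, 2, 2)),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def mixed_library(mixed_spec, tmp_path_factory) -> chemlib.CombinatorialLibrary:
    out = tmp_path_factory.mktemp("mixed-lib")
    return fixtures.load_toy_library(mixed_spec, out)


@pytest.fixture(scope="session")
def search_library(tmp_path_factory) -> chemlib.CombinatorialLibrary:
    """A 30×40 = 1200-product library for search-quality tests."""
    spec = fixtures.ToyLibrarySpec(
        reactions=(fixtures.ReactionSpec(arity=2, slot_sizes=(30, 40)),), seed=5
    )
    out = tmp_path_factory.mktemp("search-lib")
    return fixtures.load_toy_library(spec, out)


@pytest.fixture(scope="session")
def planted(search_library):
    """Noiseless planted landscape over the search library, ranking recorded."""
    landscape, config = fixtures.make_planted_landscape(
        search_library, np.random.default_rng(11)
    )
    return landscape, config
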