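"""Shared fixtures: small forms, fold sets and model builders."""

import numpy as np
import pytest

import foldbench as fb
from foldbench.decoygen import minimum_loop_lengths


@pytest.fixture(scope="session")
def form131():
    return fb.Form(1, 3, 1)


@pytest.fixture(scope="session")
def form252():
    return fb.Form(2, 5, 2)


@pytest.fixture(scope="session")
def folds131(form131):
    """All filtered folds of a 1-3-1 form with 3 strands and 2 helices."""
    return fb.enumerate_folds(form131, 2, 3)


@pytest.fixture(scope="session")
def small_fold_set(form131):
    """Folds of a 1-3-1 form with 3 strands and 1 helix (4-element strings)."""
    return fb.enumerate_folds(form131, 1, 3)


def build_fold_model(ts, form, seed=1, strand_len=5, helix_len=8, min_loop=5):
    """Build a model with standard element lengths and adequate loop slack.

    A handful of fold/seed combinations leave the self-avoiding loop walk
    boxed in at the chosen loop length; a residue of extra slack resolves
    them, so retry with progressively longer loops before giving up.
    """
    lengths = [strand_len if e.is_strand else helix_len for e in ts]
    minima = minimum_loop_lengths(ts, lengths, form)
    last = None
    for extra in range(4):
        loops = [min(15, max(min_loop, m + 1 + extra)) for m in minima]
        try:
            return fb.build_ca_model(ts, lengths, loops, seed=seed, form=form)
        except fb.BuildError as err:
            last = err
    raise last


@pytest.fixture(scope="session")
def rossmann_like(form252):
    """A canonical 5-strand, 2-helix fold and a model built from it."""
    ts = fb.parse_topology("+B+2 +A+0 +B+1 -B+0 +C+0 -B+3 +B+4").canonical()
    model = build_fold_model(ts, form252, seed=3)
    return ts, model


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
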