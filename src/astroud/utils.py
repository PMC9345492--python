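"""Reproducibility helpers shared by the simulators and the CLI."""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31 - 1


def derive_seeds(master: int, n: int) -> list[int]:
    """Derive ``n`` independent integer sub-seeds from one master seed.

    Splitting goes through :class:`numpy.random.SeedSequence`, so streams
    seeded from different children are statistically independent.  The
    returned integers are < 2**31 and can seed both NumPy generators and
    the numba kernels.
    """
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0]) % _MAX_SEED for child in ss.spawn(n)]


def spawn_generators(master: int, n: int) -> list[np.random.Generator]:
    """``n`` independent :class:`numpy.random.Generator` streams from one seed."""
    ss = np.random.SeedSequence(master)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def check_finite(name: str, value) -> None:
    """Raise ``ValueError`` naming ``name`` if ``value`` has non-finite entries."""
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {name!r}")
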