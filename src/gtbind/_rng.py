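"""Seed fan-out.

A single user-facing seed is expanded into independent named streams
(model init, fold assignment, per-epoch sampling, feature noise, fixture
generation) so that component-level reproducibility survives refactoring:
adding a draw to one component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, *names: str) -> int:
    """Derive a deterministic 31-bit sub-seed from ``seed`` and a name path."""
    h = zlib.crc32("/".join(names).encode("utf-8"))
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(h)) % np.uint64(2**31))


def rng_for(seed: int, *names: str) -> np.random.Generator:
    """A ``numpy`` Generator for the named stream under ``seed``."""
    return np.random.default_rng(subseed(seed, *names))
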