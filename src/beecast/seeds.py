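"""Deterministic seed derivation.

One global seed drives every stage of a run. Sub-streams (weather noise,
Poisson counts, per-replicate splits, permutation shuffles, ...) get their
own independent generators through a documented rule: the base seed plus a
sequence of string/int keys is fed to :class:`numpy.random.SeedSequence`,
strings being mapped to integers via a stable byte encoding. Derived seeds
are kept below 2**31 so they remain valid for every downstream consumer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % (2**32)
    return int.from_bytes(key.encode("utf-8"), "little") % (2**32)


def derive_seed(base_seed: int, *keys: str | int) -> int:
    """Derive a reproducible 31-bit seed from a base seed and a key path."""
    entropy = [int(base_seed) % (2**32)] + [_key_to_int(k) for k in keys]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def rng_for(base_seed: int, *keys: str | int) -> np.random.Generator:
    """Independent generator for the sub-stream named by ``keys``."""
    return np.random.default_rng(derive_seed(base_seed, *keys))
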