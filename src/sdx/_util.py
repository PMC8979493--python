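"""Shared helpers: deterministic sub-seeding and structured logging."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time

import numpy as np

logger = logging.getLogger("sdx")


def subseed(master: int, *tags) -> int:
    """Derive a stable 32-bit sub-seed from a master seed and string tags.

    Every stochastic stage draws its RNG from a named sub-seed so that
    reruns with the same master seed are bitwise stable regardless of
    stage ordering.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master)).encode())
    for t in tags:
        h.update(b"\x00")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big")


def rng_for(master: int, *tags) -> np.random.Generator:
    return np.random.default_rng(subseed(master, *tags))


def log_event(stage: str, **fields) -> None:
    """Emit one JSON line per stage event (auditability of budgets/seeds)."""
    rec = {"stage": stage, "ts": round(time.time(), 3), **fields}
    logger.info(json.dumps(rec, default=str))


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
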