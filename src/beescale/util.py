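"""Small shared numerics: convergence diagnostics, fingerprints, seeds."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

__all__ = ["split_rhat", "data_fingerprint", "spawn_seed"]


def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R̂ for an (n_chains, n_draws) array.

    Each chain is split in half before computing the between/within
    variance ratio, so non-stationarity within a chain also inflates the
    statistic.  Returns NaN when draws are constant (a degenerate but
    converged situation is reported as 1.0).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    n = chains.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, chains.shape[1] - n:]], axis=0)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def data_fingerprint(frame: pd.DataFrame, columns: list[str] | None = None) -> str:
    """Order-insensitive sha256 of the training table's relevant columns."""
    cols = columns if columns is not None else sorted(frame.columns)
    sub = frame[cols].copy()
    for c in sub.columns:
        if sub[c].dtype.kind == "f":
            sub[c] = sub[c].round(12)
    canon = sub.sort_values(by=list(sub.columns)).to_csv(index=False)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def spawn_seed(seed: int, *words: int | str) -> int:
    """Derive a deterministic child seed (< 2**31) from a base seed and tags."""
    h = hashlib.sha256(repr((seed, words)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
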