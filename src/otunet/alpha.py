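"""Rarefaction to even depth and per-sample alpha diversity (Shannon, Chao1).

Rarefaction subsamples each sample's reads without replacement to a common
depth so richness and evenness are compared at equal sequencing effort; the
subsample is a single seeded draw (one-shot, as is usual when a survey
rarefies once to its shallowest sample), with repeated-draw averaging
available via ``n_iterations``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

__all__ = ["rarefy", "shannon", "chao1", "alpha_diversity"]


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Each column is a multivariate-hypergeometric draw of `depth` reads from
    that sample's counts.  OTU rows that become all-zero are retained:
    dropping empty rows is a separate, explicit step.  Raises ``ValueError``
    naming the first sample whose total is below `depth`.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_sums()
    short = np.flatnonzero(totals < depth)
    if short.size:
        sid = table.sample_ids[short[0]]
        raise ValueError(
            f"sample {sid!r} has {totals[short[0]]} reads < requested depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return OtuTable(out, table.otu_ids, table.sample_ids)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions.

    Natural-log units (nats) by default; pass ``base=2`` or ``base=10`` for
    bits/dits.  Zero counts contribute nothing; an all-zero vector is a
    domain error.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), singleton/doubleton based.

    When no doubletons exist the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is used, keeping the estimate
    finite.  Always >= observed richness.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("Chao1 undefined for an all-zero sample")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


@dataclass(frozen=True)
class AlphaDiversityResult:
    """Per-sample diversity table plus the rarefaction parameters that produced it."""

    per_sample: pd.DataFrame  # index sample_id; observed_otus, shannon, chao1
    depth: int
    seed: int
    log_base: float | None = None


def alpha_diversity(table: OtuTable, depth: int | None = None, seed: int = 0,
                    log_base: float | None = None,
                    n_iterations: int = 1) -> AlphaDiversityResult:
    """Rarefy to `depth` (default: the shallowest sample) and index every sample.

    With ``n_iterations > 1`` the indices are averaged over repeated
    rarefaction draws instead of the default single draw.
    """
    if depth is None:
        depth = int(table.sample_sums().min())
    frames = []
    for it in range(n_iterations):
        r = rarefy(table, depth, seed=seed + it)
        frames.append(pd.DataFrame(
            {
                "observed_otus": (r.counts > 0).sum(axis=0),
                "shannon": [shannon(r.counts[:, j], base=log_base)
                            for j in range(r.n_samples)],
                "chao1": [chao1(r.counts[:, j]) for j in range(r.n_samples)],
            },
            index=list(table.sample_ids),
        ))
    mean = sum(frames[1:], frames[0]) / len(frames)
    mean["depth"] = depth
    mean.index.name = "sample_id"
    return AlphaDiversityResult(mean, depth=depth, seed=seed, log_base=log_base)
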