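"""Four-taxon ABBA-BABA D with block-resampled standard errors.

At a polarized biallelic site with single genomes H1, H2, H3 and the
outgroup defining the ancestral allele A, the site pattern ABBA means
(H1, H2, H3) = (ancestral, derived, derived) and BABA means
(derived, ancestral, derived).  D = (nABBA - nBABA) / (nABBA + nBABA);
an excess of one pattern class indicates gene flow between H3 and the
corresponding ingroup lineage.  For population (group) tests, patterns are
weighted by the product of group derived-allele frequencies:
nABBA += (1 - p1) * p2 * p3 and nBABA += p1 * (1 - p2) * p3, which reduces
to the single-genome counts when groups have one member.

Standard errors come from resampling 5 Mb genomic blocks: a weighted
delete-one block jackknife or a block bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genodata import BlockPartition, SiteMatrix, derived_frequencies

logger = logging.getLogger(__name__)


@dataclass
class PatternCounts:
    """Per-block weighted ABBA/BABA counts.

    ``n_abba[b]`` and ``n_baba[b]`` accumulate pattern weights over the
    sites of block ``b``; ``n_sites_used`` counts sites with all three
    H-sets covered.
    """

    n_abba: np.ndarray
    n_baba: np.ndarray
    n_sites_used: int

    @property
    def n_blocks(self) -> int:
        return len(self.n_abba)

    @property
    def totals(self) -> tuple[float, float]:
        return float(self.n_abba.sum()), float(self.n_baba.sum())


@dataclass
class StatResult:
    """A D-family statistic with its resampling uncertainty.

    ``value`` lies in [-1, 1]; ``z = value / se`` (NaN when ``se`` is zero
    or unavailable); ``n_blocks`` counts the informative blocks that entered
    resampling.
    """

    value: float
    se: float | None = None
    z: float | None = None
    n_blocks: int | None = None
    n_sites: int | None = None
    method: str | None = None
    seed: int | None = None


def _as_indices(matrix: SiteMatrix, who) -> np.ndarray:
    idx = matrix.sample_index(who)
    if idx.size == 0:
        raise ValueError("empty sample set")
    return idx


def count_patterns(
    matrix: SiteMatrix,
    h1,
    h2,
    h3,
    blocks: BlockPartition,
) -> PatternCounts:
    """Accumulate frequency-weighted ABBA/BABA counts per genomic block.

    ``h1``/``h2``/``h3`` are a sample name or an iterable of names; the
    outgroup is implicit in the polarization (ancestral = A).  Sites where
    any of the three sets is entirely missing contribute nothing.
    """
    if not matrix.polarized:
        raise ValueError("matrix must be polarized (0 = ancestral) for D")
    idx = [_as_indices(matrix, h) for h in (h1, h2, h3)]
    flat = np.concatenate(idx)
    if len(set(flat.tolist())) != len(flat):
        raise ValueError("H1/H2/H3 share a sample; sets must be disjoint")
    freqs, covered = [], []
    for ix in idx:
        f, n = derived_frequencies(matrix.calls[:, ix])
        freqs.append(f)
        covered.append(n > 0)
    ok = covered[0] & covered[1] & covered[2]
    p1, p2, p3 = (np.where(ok, f, 0.0) for f in freqs)
    w_abba = (1 - p1) * p2 * p3
    w_baba = p1 * (1 - p2) * p3
    nb = blocks.n_blocks
    bl = blocks.block_of_site
    return PatternCounts(
        n_abba=np.bincount(bl, weights=w_abba, minlength=nb),
        n_baba=np.bincount(bl, weights=w_baba, minlength=nb),
        n_sites_used=int(ok.sum()),
    )


def d_from_counts(counts: PatternCounts) -> StatResult:
    """Point estimate D = (nABBA - nBABA) / (nABBA + nBABA)."""
    na, nb = counts.totals
    tot = na + nb
    if tot <= 0:
        raise ZeroDivisionError(
            "D undefined: zero informative ABBA/BABA sites")
    return StatResult(value=(na - nb) / tot, n_sites=counts.n_sites_used)


def _weighted_jackknife(theta: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one-block jackknife standard error (Busing et al.).

    ``loo[j]`` is the statistic with block j deleted and ``weights[j]`` the
    block's informative weight (pattern-count total).
    """
    g = len(loo)
    n = weights.sum()
    h = n / weights
    theta_dot = g * theta - ((1 - weights / n) * loo).sum()
    tau = h * theta - (h - 1) * loo
    var = ((tau - theta_dot) ** 2 / (h - 1)).sum() / g
    return float(np.sqrt(var))


def block_resample(
    counts: PatternCounts,
    method: str = "jackknife",
    n_reps: int = 1000,
    seed: int | None = None,
) -> StatResult:
    """D with a block-jackknife or block-bootstrap standard error and Z.

    Blocks with zero informative weight are excluded.  Bootstrap replicate
    ``b`` draws ``n_blocks`` informative blocks with replacement using a
    generator seeded with ``seed + b``, so replicates are reproducible and
    order-independent; the SE is the standard deviation of replicate D
    values.  The jackknife uses the weighted delete-one formula with block
    weights equal to the block's pattern-count total.
    """
    na = np.asarray(counts.n_abba, dtype=float)
    nb = np.asarray(counts.n_baba, dtype=float)
    w = na + nb
    keep = w > 0
    na, nb, w = na[keep], nb[keep], w[keep]
    g = len(w)
    point = d_from_counts(counts).value
    if g < 2:
        raise ValueError("insufficient blocks: >=2 informative blocks needed")
    if method == "jackknife":
        tot_a, tot_b, tot = na.sum(), nb.sum(), w.sum()
        loo = ((tot_a - na) - (tot_b - nb)) / (tot - w)
        se = _weighted_jackknife(point, loo, w)
    elif method == "bootstrap":
        if n_reps < 2:
            raise ValueError("bootstrap needs n_reps >= 2")
        if seed is None:
            raise ValueError("bootstrap requires a seed for reproducibility")
        reps = np.empty(n_reps)
        for b in range(n_reps):
            rng = np.random.default_rng(seed + b)
            pick = rng.integers(0, g, size=g)
            sa, sb = na[pick].sum(), nb[pick].sum()
            reps[b] = (sa - sb) / (sa + sb) if sa + sb > 0 else np.nan
        reps = reps[np.isfinite(reps)]
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    if se > 0:
        z = point / se
    else:
        warnings.warn("resampling SE is 0; Z undefined", stacklevel=2)
        z = float("nan")
    return StatResult(value=point, se=se, z=z, n_blocks=g,
                      n_sites=counts.n_sites_used, method=method, seed=seed)


def d_statistic(
    matrix: SiteMatrix,
    h1,
    h2,
    h3,
    blocks: BlockPartition,
    method: str = "jackknife",
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[StatResult, PatternCounts]:
    """Convenience wrapper: count patterns then resample for SE and Z."""
    counts = count_patterns(matrix, h1, h2, h3, blocks)
    return block_resample(counts, method=method, n_reps=n_reps, seed=seed), counts
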