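"""Extended D (D_ex): lineage-specific derived-allele sharing.

Classic D conditions on a single outgroup.  D_ex instead ascertains sites
where a focal genome or population H3 carries a derived allele that is
absent (strict mode) or rare (window mode) in several conditioning
'outgroup' groups, plus always absent in a root outgroup group.  Over those
H3-specific sites the derived allele observed in the reference H1 increments
nBABA_ex and in the target H2 increments nABBA_ex, and

    D_ex = (nABBA_ex - nBABA_ex) / (nABBA_ex + nBABA_ex)

so a positive value means the target shares more H3-specific ancestry than
the reference.  Z scores come from a 5 Mb block bootstrap.  Window-mode
ascertainment also powers the "disentangling" attribution: among retained
sites shared by a target, count which conditioning individuals carry the
H3-specific allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abba_baba import PatternCounts, StatResult, block_resample
from .genodata import BlockPartition, GroupSpec, SiteMatrix, derived_frequencies

logger = logging.getLogger(__name__)


@dataclass
class DexAscertainment:
    """The retained H3-specific site set and the rules that produced it."""

    mode: str  # "strict" | "window"
    conditioning_groups: list[GroupSpec]
    root_fixed_group: GroupSpec | None
    window: tuple[float, float]
    h3: object
    retained_sites: np.ndarray  # boolean over matrix sites
    h3_fixed_derived: bool = True
    all_groups_le_high: bool = False

    @property
    def n_retained(self) -> int:
        return int(self.retained_sites.sum())


def _group_members(g) -> tuple[str, ...]:
    if isinstance(g, GroupSpec):
        return g.members
    if isinstance(g, str):
        return (g,)
    return tuple(g)


def ascertain_dex_sites(
    matrix: SiteMatrix,
    h3,
    conditioning: list,
    root_fixed=None,
    mode: str = "strict",
    window: tuple[float, float] = (0.0, 0.10),
    h3_fixed_derived: bool = True,
    all_groups_le_high: bool = False,
) -> DexAscertainment:
    """Select sites carrying an H3-specific derived allele.

    A site is retained iff

    * H3 is derived (all non-missing calls derived by default; with
      ``h3_fixed_derived=False`` any derived call suffices),
    * every conditioning group and the root-fixed group has at least one
      non-missing call ("covered at least once"),
    * strict mode: derived frequency is 0 in every conditioning group and
      in the root-fixed group;
      window mode: derived frequency is 0 in the root-fixed group and falls
      in ``(low, high]`` in at least one conditioning group (with
      ``all_groups_le_high`` the remaining groups must also stay <= high).
    """
    if not matrix.polarized:
        raise ValueError("matrix must be polarized for D_ex ascertainment")
    if mode not in ("strict", "window"):
        raise ValueError(f"mode must be 'strict' or 'window', got {mode!r}")
    if mode == "strict" and not conditioning:
        raise ValueError("strict ascertainment needs >=1 conditioning group")
    low, high = window
    if mode == "window" and not (0.0 <= low < high <= 0.5):
        raise ValueError(
            f"window bounds must satisfy 0 <= low < high <= 0.5, got {window}")

    h3_members = _group_members(h3)
    for g in conditioning:
        if set(h3_members) & set(_group_members(g)):
            raise ValueError("H3 overlaps a conditioning group")

    f3, n3 = derived_frequencies(matrix.calls[:, matrix.sample_index(h3_members)])
    if h3_fixed_derived:
        h3_ok = (n3 > 0) & (f3 == 1.0)
    else:
        h3_ok = (n3 > 0) & (f3 > 0.0)

    cond_f, cond_ok = [], np.ones(matrix.n_sites, dtype=bool)
    for g in conditioning:
        f, n = derived_frequencies(
            matrix.calls[:, matrix.sample_index(_group_members(g))])
        cond_f.append(f)
        cond_ok &= n > 0

    keep = h3_ok & cond_ok
    if root_fixed is not None:
        fr, nr = derived_frequencies(
            matrix.calls[:, matrix.sample_index(_group_members(root_fixed))])
        keep &= (nr > 0) & (fr == 0.0)
    elif mode == "window":
        raise ValueError("window mode requires a root-fixed group")

    if mode == "strict":
        for f in cond_f:
            keep &= f == 0.0
    else:
        in_window = np.zeros(matrix.n_sites, dtype=bool)
        for f in cond_f:
            in_window |= (f > low) & (f <= high)
            if all_groups_le_high:
                keep &= f <= high
        keep &= in_window

    groups = [g if isinstance(g, GroupSpec)
              else GroupSpec(name=str(g), members=_group_members(g),
                             role="conditioning")
              for g in conditioning]
    return DexAscertainment(
        mode=mode, conditioning_groups=groups, root_fixed_group=root_fixed,
        window=(low, high), h3=h3, retained_sites=keep,
        h3_fixed_derived=h3_fixed_derived, all_groups_le_high=all_groups_le_high,
    )


def dex_counts(
    matrix: SiteMatrix,
    ascertainment: DexAscertainment,
    h1,
    h2,
    blocks: BlockPartition,
) -> PatternCounts:
    """Per-block nABBA_ex / nBABA_ex over the ascertained sites.

    Per retained site covered in both H1 and H2, nBABA_ex gains the H1
    derived-allele frequency and nABBA_ex the H2 frequency (0/1 for single
    genomes).  The PatternCounts container is shared with classic D so the
    same resampling machinery applies.
    """
    h1_m, h2_m = _group_members(h1), _group_members(h2)
    h3_m = _group_members(ascertainment.h3)
    reserved = set(h3_m)
    for g in ascertainment.conditioning_groups:
        reserved |= set(g.members)
    if (set(h1_m) | set(h2_m)) & reserved:
        raise ValueError(
            "H1/H2 must be disjoint from H3 and the conditioning groups")
    f1, n1 = derived_frequencies(matrix.calls[:, matrix.sample_index(h1_m)])
    f2, n2 = derived_frequencies(matrix.calls[:, matrix.sample_index(h2_m)])
    ok = ascertainment.retained_sites & (n1 > 0) & (n2 > 0)
    w_baba = np.where(ok, f1, 0.0)
    w_abba = np.where(ok, f2, 0.0)
    nb = blocks.n_blocks
    return PatternCounts(
        n_abba=np.bincount(blocks.block_of_site, weights=w_abba, minlength=nb),
        n_baba=np.bincount(blocks.block_of_site, weights=w_baba, minlength=nb),
        n_sites_used=int(ok.sum()),
    )


def dex_statistic(
    matrix: SiteMatrix,
    ascertainment: DexAscertainment,
    h1,
    h2,
    blocks: BlockPartition,
    method: str = "bootstrap",
    n_reps: int = 1000,
    seed: int | None = 0,
) -> tuple[StatResult, PatternCounts]:
    """D_ex with a block-bootstrap (default, 1000 reps) or jackknife Z."""
    counts = dex_counts(matrix, ascertainment, h1, h2, blocks)
    if counts.totals[0] + counts.totals[1] <= 0:
        raise ZeroDivisionError(
            "D_ex undefined: no retained site is shared by H1 or H2")
    res = block_resample(counts, method=method, n_reps=n_reps, seed=seed)
    return res, counts


def disentangle_attribution(
    matrix: SiteMatrix,
    ascertainment: DexAscertainment,
    h2: str,
    outgroup_individuals: list[str],
) -> pd.DataFrame:
    """Attribute a target's shared H3-specific alleles to outgroup individuals.

    Restricts to window-mode retained sites where ``h2`` carries the derived
    allele (the "shared variants"); for each listed individual, counts the
    sites where that individual is also derived.  Returns one row per
    individual with the raw count, the number of shared-variant sites at
    which the individual is non-missing, and two proportions: of all shared
    sites (default) and of the total sharing observations summed over
    individuals.
    """
    if ascertainment.mode != "window":
        raise ValueError("disentangling requires window-mode ascertainment")
    h2_idx = matrix.sample_index(h2)
    h2_calls = matrix.calls[:, h2_idx]
    h2_derived = (h2_calls == 1).any(axis=1)
    shared = ascertainment.retained_sites & h2_derived
    n_shared = int(shared.sum())
    rows = []
    for ind in outgroup_individuals:
        c = matrix.calls[shared, matrix.sample_index(ind)[0]]
        rows.append({
            "individual": ind,
            "n_derived": int((c == 1).sum()),
            "n_nonmissing": int((c >= 0).sum()),
        })
    df = pd.DataFrame(rows)
    df["n_shared_sites"] = n_shared
    if n_shared == 0:
        warnings.warn(f"no shared H3-specific sites for target {h2!r}",
                      stacklevel=2)
        df["prop_of_sites"] = np.nan
        df["prop_of_observations"] = np.nan
        return df
    df["prop_of_sites"] = df["n_derived"] / n_shared
    tot_obs = df["n_derived"].sum()
    df["prop_of_observations"] = (
        df["n_derived"] / tot_obs if tot_obs > 0 else np.nan)
    return df


def attribution_matrix(
    matrix: SiteMatrix,
    ascertainment: DexAscertainment,
    h2_targets: list[str],
    outgroup_individuals: list[str],
    proportion: str = "prop_of_sites",
) -> pd.DataFrame:
    """Targets x outgroup-individuals table of sharing proportions
    (the long-format input behind the disentangling heatmap)."""
    cols = {}
    for h2 in h2_targets:
        df = disentangle_attribution(matrix, ascertainment, h2,
                                     outgroup_individuals)
        cols[h2] = df.set_index("individual")[proportion]
    return pd.DataFrame(cols).T


def correlate_result_sets(a, b) -> float:
    """Pearson r between two matched vectors of statistic values.

    Used to compare a battery of D/D_ex tests across ascertainments or
    reference alignments.  Returns NaN with a warning when either vector
    has zero variance.
    """
    a = np.asarray([x.value if isinstance(x, StatResult) else x for x in a],
                   dtype=float)
    b = np.asarray([x.value if isinstance(x, StatResult) else x for x in b],
                   dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("result vectors must be matched 1-D arrays")
    if len(a) < 3:
        raise ValueError("need >=3 matched results to correlate")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
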