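"""Identity-by-state distances, neighbour-joining trees, pseudo-bootstrap
node supports, classical MDS, and outgroup-distance QC.

IBS distance between two pseudo-haploid samples is the proportion of
mismatching calls among sites where both are called (per-pair deletion).
Trees are built with the Saitou-Nei neighbour-joining algorithm,
reimplemented here with a deterministic tie-break (lowest index pair in the
Q matrix) and negative branch lengths clamped to zero; node supports come
from a region pseudo-bootstrap that resamples 5 Mb genomic blocks without
replacement and transfers bipartition frequencies onto the all-sites base
tree.  Classical (Torgerson) MDS embeds the distance matrix for the usual
two-axis ordination plot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .genodata import BlockPartition, SiteMatrix, filter_sites

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise IBS mismatch proportions with co-called counts."""

    labels: list[str]
    d: np.ndarray            # (n, n) float, NaN where undefined
    n_compared: np.ndarray   # (n, n) int co-called site counts

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        bad = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    bad.append((self.labels[i], self.labels[j]))
        return bad

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_ibsmat(self, path, labeled: bool = False) -> None:
        """Square TSV mirroring the ANGSD .ibsMat layout (no header) or a
        labeled variant."""
        df = self.to_frame()
        if labeled:
            df.to_csv(path, sep="\t")
        else:
            df.to_csv(path, sep="\t", header=False, index=False)


def ibs_matrix(
    matrix: SiteMatrix,
    region: tuple[str, int, int] | None = None,
    samples: list[str] | None = None,
    **filter_kwargs,
) -> DistanceMatrix:
    """Pairwise IBS mismatch proportions over (optionally filtered and
    region-restricted) sites.

    ``region`` is (chrom, start, end), 1-based fully closed.  Any keyword
    accepted by :func:`ghostdex.genodata.filter_sites` may be passed.
    """
    m = matrix
    if filter_kwargs:
        m = filter_sites(m, **filter_kwargs)
    if region is not None:
        chrom, start, end = region
        keep = ((m.sites["chrom"] == str(chrom))
                & (m.sites["pos"] >= int(start))
                & (m.sites["pos"] <= int(end))).to_numpy()
        m = m.take_sites(keep)
    if samples is not None:
        cols = m.sample_index(samples)
        labels = list(samples)
        calls = m.calls[:, cols]
    else:
        labels = list(m.samples)
        calls = m.calls
    if len(labels) < 2:
        raise ValueError("IBS needs at least two samples")
    called = (calls >= 0).astype(np.float64)
    x = np.where(calls == 1, 1.0, 0.0) * called
    n_co = called.T @ called
    # mismatches where both called: one derived, the other ancestral
    mism = x.T @ called + called.T @ x - 2.0 * (x.T @ x)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_co > 0, mism / np.maximum(n_co, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d,
                          n_compared=n_co.astype(np.int64))


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dm: DistanceMatrix, root_on: str | None = None) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Q-matrix ties are broken by the lowest (i, j) pair in current matrix
    order; negative branch lengths are clamped to 0 with a warning.  The
    returned tree is unrooted (trifurcating root) unless ``root_on`` names
    a leaf to use as outgroup.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"undefined IBS pairs (no co-called sites): {bad}")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >=3 labels")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    clamped = 0

    def _set_len(node: TreeNode, length: float):
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        node.length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin on the flattened row-major array -> lowest (i, j) on ties
        k = int(np.argmin(q))
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        _set_len(nodes[active[i]], li)
        _set_len(nodes[active[j]], lj)
        parent.append(nodes[active[i]])
        parent.append(nodes[active[j]])
        # distances from the new node to every remaining taxon
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            d[new_idx, at] = d[at, new_idx] = 0.5 * (
                sub[i, t] + sub[j, t] - dij)
        ai, aj = active[i], active[j]
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    # join the final three nodes on a central trifurcation
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = TreeNode()
    _set_len(nodes[a], 0.5 * (dab + dac - dbc))
    _set_len(nodes[b], 0.5 * (dab + dbc - dac))
    _set_len(nodes[c], 0.5 * (dac + dbc - dab))
    for x in (a, b, c):
        root.append(nodes[x])
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0",
                      stacklevel=2)
    if root_on is not None:
        root = root.root_by_outgroup([root_on])
    return root


def tree_bipartitions(tree: TreeNode, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized to
    the side not containing the first label."""
    full = frozenset(labels)
    ref = labels[0]
    out = set()
    for s in tree.subsets():
        side = frozenset(s)
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def node_support_pseudobootstrap(
    matrix: SiteMatrix,
    blocks: BlockPartition,
    n_regions: int = 50,
    n_reps: int = 100,
    seed: int = 0,
    region: tuple[str, int, int] | None = None,
    samples: list[str] | None = None,
    **filter_kwargs,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ base tree with region pseudo-bootstrap bipartition supports.

    Each replicate samples ``n_regions`` distinct genomic blocks without
    replacement, computes IBS over their sites and builds an NJ tree; the
    support of each internal edge of the all-sites base tree is the
    percentage of replicate trees containing that bipartition.  Supports are
    written as internal node names on the returned tree.
    """
    nonempty = np.flatnonzero(np.bincount(
        blocks.block_of_site, minlength=blocks.n_blocks) > 0)
    if len(nonempty) < n_regions:
        raise ValueError(
            f"only {len(nonempty)} non-empty blocks < n_regions={n_regions}; "
            "reduce n_regions")
    base_dm = ibs_matrix(matrix, region=region, samples=samples,
                         **filter_kwargs)
    base = nj_tree(base_dm)
    labels = base_dm.labels
    base_bip = tree_bipartitions(base, labels)
    counts = {bp: 0 for bp in base_bip}
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        pick = rng.choice(nonempty, size=n_regions, replace=False)
        keep = np.isin(blocks.block_of_site, pick)
        sub = matrix.take_sites(keep)
        rep_dm = ibs_matrix(sub, region=region, samples=samples,
                            **filter_kwargs)
        rep_bip = tree_bipartitions(nj_tree(rep_dm), labels)
        for bp in base_bip & rep_bip:
            counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    full = frozenset(labels)
    ref = labels[0]
    for node in base.non_tips(include_self=False):
        side = frozenset(node.subset())
        if ref in side:
            side = full - side
        if side in supports:
            node.name = f"{supports[side]:g}"
    return base, supports


# ---------------------------------------------------------------------------
# Classical MDS


def classical_mds(dm: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix, takes the top-k eigenpairs
    and scales eigenvectors by sqrt(eigenvalue).  The sign of each axis is
    fixed so its largest-magnitude loading is positive.  Negative
    eigenvalues among the top k (non-Euclidean input) trigger a warning and
    contribute zero coordinates.
    """
    n = len(dm.labels)
    if k >= n:
        raise ValueError(f"k={k} must be < number of labels ({n})")
    if dm.undefined_pairs():
        raise ValueError("MDS requires a fully defined distance matrix")
    d2 = dm.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    if (lam < -1e-10).any():
        warnings.warn("negative eigenvalues among top-k axes "
                      "(non-Euclidean distances)", stacklevel=2)
    coords = evecs[:, order] * np.sqrt(np.clip(lam, 0, None))
    for a in range(k):
        col = coords[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    return pd.DataFrame(coords, index=dm.labels,
                        columns=[f"axis{a + 1}" for a in range(k)])


def outgroup_distance_qc(
    dm: DistanceMatrix,
    outgroup: str,
    groups: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Distance-to-outgroup QC table.

    High-error samples inflate their IBS distance from the outgroup, so each
    sample's d(sample, outgroup) is compared with its group peers (all other
    non-outgroup members of the same group): samples beyond the peer mean
    +/- 3 peer sd are flagged high/low.
    """
    if outgroup not in dm.labels:
        raise ValueError(f"outgroup {outgroup!r} not in matrix labels")
    gi = dm.labels.index(outgroup)
    rows = []
    gmap = dict(groups) if groups is not None else {}
    for i, lab in enumerate(dm.labels):
        if lab == outgroup:
            continue
        rows.append({"sample": lab, "group": gmap.get(lab, "all"),
                     "dist_to_outgroup": dm.d[i, gi]})
    df = pd.DataFrame(rows)
    means, sds, flags = [], [], []
    for _, row in df.iterrows():
        peers = df[(df["group"] == row["group"])
                   & (df["sample"] != row["sample"])]["dist_to_outgroup"]
        mu = peers.mean() if len(peers) else np.nan
        sd = peers.std(ddof=1) if len(peers) > 1 else np.nan
        means.append(mu)
        sds.append(sd)
        if len(peers) > 1 and np.isfinite(sd) and sd > 0:
            if row["dist_to_outgroup"] > mu + 3 * sd:
                flags.append("high")
            elif row["dist_to_outgroup"] < mu - 3 * sd:
                flags.append("low")
            else:
                flags.append("")
        else:
            flags.append("")
    df["peer_mean"] = means
    df["peer_sd"] = sds
    df["flag"] = flags
    return df
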