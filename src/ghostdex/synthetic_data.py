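"""Synthetic pseudo-haploid genotype matrices and mtDNA alignments with
full ground truth.

The genotype generator evolves per-site derived-allele frequencies down a
population tree by Balding-Nichols drift (one beta draw per branch, with
fixation absorbing), optionally mixes in a "ghost" lineage at proportion
``alpha`` into a target population (genome-wide or confined to one genomic
region), and then emulates the pseudo-haploid observation process: one
allele sampled per site per sample from its population frequency, flipped
with a per-call error rate and masked at one minus the call rate.  Every
emitted site carries a truth record (root allele, per-population
frequencies, ghost-admixture flag), so statistics computed downstream can
be checked against the generating model.

The mtDNA generator drops Jukes-Cantor substitutions (Poisson-distributed
per branch) along a given tree from a random root sequence and N-masks
each leaf at a stated rate, emulating low-coverage consensus calling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .genodata import (
    MISSING,
    SITE_COLUMNS,
    GroupSpec,
    SiteMatrix,
    write_groups,
    write_site_annotations,
    write_tped,
)

_NUCS = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ["C", "T"], "G": ["C", "T"],
                  "C": ["A", "G"], "T": ["A", "G"]}


@dataclass
class SimScenario:
    """A simulation scenario: population tree, ghost admixture, sampling.

    ``edges`` lists (parent, child, drift) triples; drift is the
    Balding-Nichols F of the branch (0 = copy the parent frequency).
    Populations are the tree leaves named in ``sample_sizes``.  ``groups``
    optionally lists (name, member sample names, role) triples; when
    omitted, one role-less group per population is emitted.  Sample names
    are ``{pop}_{i:02d}``.
    """

    edges: tuple
    sample_sizes: dict
    chromosomes: dict
    n_sites: int
    seed: int
    root: str = "root"
    ghost_pop: str | None = None
    admix_target: str | None = None
    alpha: float = 0.0
    ghost_region: tuple | None = None  # (chrom, start, end), else genome-wide
    call_rate: float = 0.9
    error_rate: float = 0.001
    transition_fraction: float = 2.0 / 3.0
    cpg_fraction: float = 0.05
    root_freq_range: tuple = (0.05, 0.95)
    groups: tuple | None = None
    name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 < self.call_rate <= 1.0:
            raise ValueError("call_rate must be in (0, 1]")
        if any(f < 0 for _, _, f in self.edges):
            raise ValueError("drift parameters must be >= 0")
        if self.alpha > 0:
            if self.ghost_pop is None or self.admix_target is None:
                raise ValueError("alpha > 0 needs ghost_pop and admix_target")
            leaves = self._leaves()
            if len(leaves) < 2:
                raise ValueError(
                    "degenerate tree: admixture needs >=2 populations")

    def _children(self) -> dict:
        ch: dict[str, list] = {}
        for parent, child, f in self.edges:
            ch.setdefault(parent, []).append((child, f))
        return ch

    def _leaves(self) -> list[str]:
        parents = {p for p, _, _ in self.edges}
        return [c for _, c, _ in self.edges if c not in parents]

    def sample_names(self) -> dict:
        return {pop: [f"{pop}_{i:02d}" for i in range(n)]
                for pop, n in self.sample_sizes.items()}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        d = json.loads(text)
        d["edges"] = tuple(tuple(e) for e in d["edges"])
        if d.get("groups"):
            d["groups"] = tuple((g[0], tuple(g[1]), g[2])
                                for g in d["groups"])
        if d.get("ghost_region"):
            d["ghost_region"] = tuple(d["ghost_region"])
        if "root_freq_range" in d:
            d["root_freq_range"] = tuple(d["root_freq_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth per emitted site."""

    root_allele: np.ndarray          # ancestral nucleotide per site
    derived_allele: np.ndarray
    pop_freqs: dict                  # population -> derived frequency array
    ghost_admixed: np.ndarray        # bool: site subject to ghost admixture
    group_of_sample: dict = field(default_factory=dict)

    def to_frame(self, sites: pd.DataFrame) -> pd.DataFrame:
        out = sites[["chrom", "pos"]].copy()
        out["root_allele"] = self.root_allele
        out["derived_allele"] = self.derived_allele
        out["ghost_admixed"] = self.ghost_admixed
        for pop, f in self.pop_freqs.items():
            out[f"freq_{pop}"] = f
        return out


def _balding_nichols(p: np.ndarray, f: float, rng) -> np.ndarray:
    """One generation of drift: Beta(p(1-F)/F, (1-p)(1-F)/F); fixation is
    absorbing and F=0 copies the parent frequency."""
    if f <= 0:
        return p.copy()
    out = p.copy()
    interior = (p > 0) & (p < 1)
    if interior.any():
        a = p[interior] * (1 - f) / f
        b = (1 - p[interior]) * (1 - f) / f
        out[interior] = rng.beta(a, b)
    return out


def _unique_positions(rng, length: int, n: int) -> np.ndarray:
    if n > length:
        raise ValueError(f"cannot place {n} sites on a {length} bp chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def simulate_scenario(scn: SimScenario
                      ) -> tuple[SiteMatrix, SimTruth, list[GroupSpec]]:
    """Simulate a pseudo-haploid SiteMatrix with full truth.

    The returned matrix is *unpolarized* (allele_a/allele_b are in random
    orientation) but carries the true ancestral nucleotide in its site
    annotations, so ``genodata.polarize`` recovers the generator's root
    allele at every site.
    """
    rng = np.random.default_rng(scn.seed)
    n = scn.n_sites

    # genome coordinates, chromosome-sorted so site order is final
    chrom_names = sorted(scn.chromosomes)
    total_len = sum(scn.chromosomes.values())
    chroms, positions = [], []
    remaining = n
    for i, c in enumerate(chrom_names):
        share = (round(n * scn.chromosomes[c] / total_len)
                 if i < len(chrom_names) - 1 else remaining)
        share = min(share, remaining)
        pos = _unique_positions(rng, scn.chromosomes[c], share)
        chroms.append(np.full(share, c, dtype=object))
        positions.append(pos)
        remaining -= share
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)

    # allele frequencies down the tree
    lo, hi = scn.root_freq_range
    freqs = {scn.root: rng.uniform(lo, hi, size=n)}
    children = scn._children()
    stack = [scn.root]
    while stack:
        node = stack.pop()
        for child, f in children.get(node, []):
            freqs[child] = _balding_nichols(freqs[node], f, rng)
            stack.append(child)

    admixed_mask = np.zeros(n, dtype=bool)
    if scn.alpha > 0:
        if scn.ghost_region is None:
            admixed_mask[:] = True
        else:
            rc, rs, re = scn.ghost_region
            admixed_mask = ((chrom_arr == str(rc)) & (pos_arr >= int(rs))
                            & (pos_arr <= int(re)))
        tgt = freqs[scn.admix_target]
        freqs[scn.admix_target] = np.where(
            admixed_mask,
            (1 - scn.alpha) * tgt + scn.alpha * freqs[scn.ghost_pop],
            tgt)

    # pseudo-haploid observation process
    names = scn.sample_names()
    sample_order = [s for pop in scn.sample_sizes for s in names[pop]]
    calls = np.empty((n, len(sample_order)), dtype=np.int8)
    col = 0
    for pop in scn.sample_sizes:
        k = scn.sample_sizes[pop]
        f = freqs[pop]
        derived = rng.random((n, k)) < f[:, None]
        flip = rng.random((n, k)) < scn.error_rate
        obs = (derived ^ flip).astype(np.int8)
        miss = rng.random((n, k)) >= scn.call_rate
        obs[miss] = MISSING
        calls[:, col:col + k] = obs
        col += k

    # site alleles: ancestral uniform; derived transition/transversion mix
    anc = _NUCS[rng.integers(0, 4, size=n)]
    is_ts = rng.random(n) < scn.transition_fraction
    tv_pick = rng.integers(0, 2, size=n)
    der = np.where(
        is_ts,
        np.vectorize(_TRANSITION.get)(anc),
        np.array([_TRANSVERSIONS[a][t] for a, t in zip(anc, tv_pick)]),
    )
    cpg = rng.random(n) < scn.cpg_fraction

    # emit in random A/B orientation so polarization is exercised
    swap = rng.random(n) < 0.5
    allele_a = np.where(swap, der, anc)
    allele_b = np.where(swap, anc, der)
    out_calls = calls.copy()
    flip_cols = out_calls[swap]
    called = flip_cols >= 0
    flip_cols[called] = 1 - flip_cols[called]
    out_calls[swap] = flip_cols

    sites = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr,
        "allele_a": allele_a, "allele_b": allele_b,
        "ancestral": anc, "is_cpg": cpg,
    })[SITE_COLUMNS]
    matrix = SiteMatrix(sites=sites, samples=sample_order, calls=out_calls)

    if scn.groups is not None:
        groups = [GroupSpec(name=g, members=tuple(m), role=r)
                  for g, m, r in scn.groups]
    else:
        groups = [GroupSpec(name=pop, members=tuple(names[pop]), role="none")
                  for pop in scn.sample_sizes]
    g_of_s = {s: g.name for g in groups for s in g.members}
    truth = SimTruth(root_allele=anc, derived_allele=der,
                     pop_freqs={p: freqs[p] for p in scn.sample_sizes},
                     ghost_admixed=admixed_mask, group_of_sample=g_of_s)
    return matrix, truth, groups


def write_scenario_outputs(outdir, matrix: SiteMatrix, truth: SimTruth,
                           groups: list[GroupSpec]) -> dict:
    """Write tped/tfam, site TSV, group TSV and truth TSV; return paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tped": outdir / "sim.tped",
        "tfam": outdir / "sim.tfam",
        "sites": outdir / "sim.sites.tsv",
        "groups": outdir / "sim.groups.tsv",
        "truth": outdir / "sim.truth.tsv",
    }
    write_tped(matrix, paths["tped"], paths["tfam"])
    write_site_annotations(matrix, paths["sites"])
    write_groups(groups, paths["groups"])
    with open(paths["truth"], "w") as fh:
        df = truth.to_frame(matrix.sites)
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# mtDNA simulator


def simulate_mtdna(tree, seq_length: int, rate: float = 1.0,
                   n_mask_rate: float = 0.0, seed: int = 0):
    """Jukes-Cantor evolution of mtDNA consensus sequences along a tree.

    ``tree`` is a newick string or skbio TreeNode with branch lengths in
    expected substitutions per site (scaled by ``rate``).  Substitution
    counts per branch are Poisson(length * rate * seq_length), positions
    uniform (multiple hits allowed), targets uniform among the three other
    bases.  Each leaf sequence is independently N-masked at
    ``n_mask_rate``.  Returns (MtAlignment, tree).
    """
    from .mtdna import MtAlignment

    if rate < 0 or n_mask_rate < 0 or n_mask_rate > 1:
        raise ValueError("rate must be >= 0 and n_mask_rate in [0, 1]")
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs = {id(tree): root_seq}
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        d = (node.length or 0.0) * rate
        n_sub = rng.poisson(d * seq_length)
        seq = parent_seq.copy()
        for _ in range(n_sub):
            p = rng.integers(0, seq_length)
            seq[p] = (seq[p] + rng.integers(1, 4)) % 4
        seqs[id(node)] = seq
    labels, out = [], []
    for leaf in tree.tips():
        s = _NUCS[seqs[id(leaf)]].copy()
        if n_mask_rate > 0:
            s[rng.random(seq_length) < n_mask_rate] = "N"
        labels.append(str(leaf.name))
        out.append("".join(s))
    return MtAlignment(labels=labels, seqs=out), tree


# ---------------------------------------------------------------------------
# Preset scenarios


def _ghost_topology() -> tuple:
    """Outgroup + ghost sister to a two-population clade (the tur pair),
    with an ingroup clade (bezoar + domestics) receiving the admixture."""
    return (
        ("root", "sheep_like", 0.30),
        ("root", "capra", 0.05),
        ("capra", "wild", 0.10),
        ("capra", "bezoar_clade", 0.05),
        ("wild", "ghost", 0.35),
        ("wild", "tur_anc", 0.05),
        ("tur_anc", "tur1", 0.10),
        ("tur_anc", "tur2", 0.10),
        ("bezoar_clade", "bezoar", 0.10),
        ("bezoar_clade", "domestic", 0.05),
        ("domestic", "dom_ref", 0.05),
        ("domestic", "dom_test", 0.05),
    )


_GHOST_GROUPS = (
    ("sheep_grp", tuple(f"sheep_like_{i:02d}" for i in range(4)),
     "root_outgroup"),
    ("tur_grp", ("tur1_00", "tur1_01", "tur2_00", "tur2_01"), "conditioning"),
    ("bezoar_grp", tuple(f"bezoar_{i:02d}" for i in range(4)), "conditioning"),
    ("ref_grp", tuple(f"dom_ref_{i:02d}" for i in range(4)), "H1"),
    ("test_grp", ("dom_test_00",), "H2"),
    ("focal_grp", ("ghost_00",), "H3"),
    ("ghost_rest", tuple(f"ghost_{i:02d}" for i in range(1, 6)), "none"),
)

_TEN_CHROMS = {f"c{i:02d}": 100_000_000 for i in range(1, 11)}


def preset_library(name: str, seed: int = 0) -> SimScenario:
    """Documented, seeded scenarios used throughout the test battery.

    * ``null_panmictic`` — one panmictic population carved into role groups;
      all samples exchangeable, so every D and D_ex test has expectation 0.
      200 five-megabase blocks over a 1 Gb genome, 500k sites.
    * ``tur_like_ghost`` — the ghost lineage is sister to a two-population
      clade (the tur-pair analogue); one domestic population receives
      alpha = 0.1 ghost ancestry genome-wide.  H3 is a single ghost sample;
      five further ghost samples are held out (group ``ghost_rest``) so the
      ghost population itself can be added to the conditioning set.
    * ``introgressed_block`` — same topology, but ghost ancestry
      (alpha = 0.8, a near-fixed introgressed haplotype) is confined to the
      first 5 Mb block of chromosome c01, for region-restricted IBS tests.
    """
    if name == "null_panmictic":
        samples = [f"P_{i:02d}" for i in range(16)]
        return SimScenario(
            name=name,
            edges=(("root", "P", 0.05),),
            sample_sizes={"P": 16},
            chromosomes=dict(_TEN_CHROMS),
            n_sites=500_000,
            call_rate=0.9,
            error_rate=0.001,
            groups=(
                ("ref_grp", tuple(samples[0:4]), "H1"),
                ("test_grp", (samples[4],), "H2"),
                ("focal_grp", (samples[5],), "H3"),
                ("outA", tuple(samples[6:9]), "conditioning"),
                ("outB", tuple(samples[9:12]), "conditioning"),
                ("root_grp", tuple(samples[12:16]), "root_outgroup"),
            ),
            seed=seed,
        )
    if name == "tur_like_ghost":
        return SimScenario(
            name=name,
            edges=_ghost_topology(),
            sample_sizes={"sheep_like": 4, "ghost": 6, "tur1": 2, "tur2": 2,
                          "bezoar": 4, "dom_ref": 4, "dom_test": 2},
            chromosomes=dict(_TEN_CHROMS),
            n_sites=1_000_000,
            ghost_pop="ghost",
            admix_target="dom_test",
            alpha=0.10,
            call_rate=0.9,
            error_rate=0.001,
            groups=_GHOST_GROUPS,
            seed=seed,
        )
    if name == "introgressed_block":
        return SimScenario(
            name=name,
            edges=_ghost_topology(),
            sample_sizes={"sheep_like": 2, "ghost": 2, "tur1": 2, "tur2": 2,
                          "bezoar": 2, "dom_ref": 3, "dom_test": 1},
            chromosomes={f"c{i:02d}": 50_000_000 for i in range(1, 5)},
            n_sites=100_000,
            ghost_pop="ghost",
            admix_target="dom_test",
            alpha=0.80,
            ghost_region=("c01", 1, 5_000_000),
            call_rate=0.95,
            error_rate=0.001,
            groups=None,
            seed=seed,
        )
    raise ValueError(
        f"unknown preset {name!r}; available: null_panmictic, "
        "tur_like_ghost, introgressed_block")
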