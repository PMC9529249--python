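"""Pseudo-haploid genotype matrices: reading, polarization, filtering, blocking.

The central container is :class:`SiteMatrix`: an ordered table of biallelic
sites with per-site annotations (chromosome, position, the two alleles, the
outgroup/ancestral nucleotide, transversion and CpG flags) and an integer
call matrix with one haploid call per sample per site.  Calls are coded
``0``/``1``/``-1`` (missing).  Before polarization code 0 means
``allele_a``; after :func:`polarize` code 0 is the ancestral (outgroup)
allele at every retained site.

Input dialects are the PLINK transposed text pair (``.tped``/``.tfam``) as
written by haploid callers (two identical allele tokens per sample per
site), a site-annotation TSV, and a group-assignment TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: tokens that encode a missing haploid call in tped output dialects
_MISSING_TOKENS = {"0", "N"}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

SITE_COLUMNS = ["chrom", "pos", "allele_a", "allele_b", "ancestral", "is_cpg"]

ROLES = {"H1", "H2", "H3", "conditioning", "root_outgroup", "none"}


def is_transversion(allele_a: str, allele_b: str) -> bool:
    """True unless the allele pair is A/G or C/T (a transition)."""
    pair = {allele_a, allele_b}
    return not (pair == _PURINES or pair == _PYRIMIDINES)


@dataclass(frozen=True)
class GroupSpec:
    """A named group of samples with an optional analysis role.

    Roles mirror the four-taxon test layout: ``H1`` (reference), ``H2``
    (target), ``H3`` (ascertainment genome/population), ``conditioning``
    (the multiple 'outgroups' whose ancestral fixation defines
    lineage-specific variants) and ``root_outgroup`` (the taxon that is
    always required to be fixed ancestral, the sheep analogue).
    """

    name: str
    members: tuple[str, ...]
    role: str = "none"

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; valid: {sorted(ROLES)}")


@dataclass
class BlockPartition:
    """Assignment of sites to contiguous genomic blocks for resampling.

    ``block_of_site[i]`` is a dense 0-based block index; sites on different
    chromosomes never share a block and within a chromosome the raw bin is
    ``floor((pos - 1) / block_size)``.  Only non-empty blocks carry an index.
    """

    block_size: int
    block_of_site: np.ndarray  # (n_sites,) int64, dense block index
    n_blocks: int
    block_keys: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SiteMatrix:
    """Biallelic sites x samples of pseudo-haploid calls.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, allele_a, allele_b,
        ancestral, is_cpg, is_transversion``; sorted by (chrom, pos).
    samples : list of str
        Sample identifiers in call-column order.
    calls : numpy.ndarray of int8, shape (n_sites, n_samples)
        0 = allele_a (ancestral once polarized), 1 = allele_b (derived),
        -1 = missing.
    polarized : bool
        Whether code 0 is guaranteed to be the ancestral allele.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    polarized: bool = False

    def __post_init__(self):
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if "is_transversion" not in self.sites.columns:
            self.sites = self.sites.copy()
            self.sites["is_transversion"] = [
                is_transversion(a, b)
                for a, b in zip(self.sites["allele_a"], self.sites["allele_b"])
            ]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names) -> np.ndarray:
        """Column indices for one sample name or an iterable of names."""
        if isinstance(names, str):
            names = [names]
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def take_sites(self, keep) -> "SiteMatrix":
        """New SiteMatrix restricted to a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SiteMatrix(
            sites=self.sites.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[keep],
            polarized=self.polarized,
        )

    def sort_sites(self) -> "SiteMatrix":
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["chrom"].to_numpy()))
        return self.take_sites(order)


# ---------------------------------------------------------------------------
# Readers / writers


def _collapse_tokens(tok1: str, tok2: str, chrom: str, pos, sample: str) -> str | None:
    """Collapse a duplicated-token haploid genotype to one allele or None."""
    m1, m2 = tok1 in _MISSING_TOKENS, tok2 in _MISSING_TOKENS
    if m1 and m2:
        return None
    if tok1 != tok2:
        raise ValueError(
            f"discordant haploid tokens {tok1!r}/{tok2!r} at {chrom}:{pos} "
            f"for sample {sample!r}"
        )
    return tok1


def read_tfam(tfam_path) -> list[str]:
    """Sample identifiers (column 2, the within-family ID) in file order."""
    samples = []
    with open(tfam_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1] if len(parts) > 1 else parts[0])
    return samples


def read_tped(tped_path, tfam_path) -> SiteMatrix:
    """Read a haploid-caller PLINK transposed-text pair into a SiteMatrix.

    Each sample occupies two allele tokens per row; a haploid call is the
    duplicated token, ``0 0`` or ``N N`` is missing, and discordant
    non-missing tokens are a hard error.  Sites with more than two observed
    alleles are rejected with a logged warning; the two site alleles are
    inferred from the observed non-missing tokens.
    """
    samples = read_tfam(tfam_path)
    n = len(samples)
    rows, call_rows = [], []
    n_rejected = 0
    with open(tped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4 + 2 * n:
                raise ValueError(
                    f"{tped_path} line {ln}: expected {4 + 2 * n} fields for "
                    f"{n} samples, got {len(parts)}"
                )
            chrom, _sid, _cm, pos = parts[:4]
            toks = parts[4:]
            alleles_here = []
            calls_here = []
            for j in range(n):
                a = _collapse_tokens(toks[2 * j], toks[2 * j + 1],
                                     chrom, pos, samples[j])
                calls_here.append(a)
                if a is not None and a not in alleles_here:
                    alleles_here.append(a)
            if len(alleles_here) > 2:
                logger.warning(
                    "rejecting site %s:%s with %d alleles %s",
                    chrom, pos, len(alleles_here), alleles_here,
                )
                n_rejected += 1
                continue
            while len(alleles_here) < 2:
                alleles_here.append("N")  # monomorphic/empty site placeholder
            a0, a1 = alleles_here[0], alleles_here[1]
            codes = np.full(n, MISSING, dtype=np.int8)
            for j, a in enumerate(calls_here):
                if a is not None:
                    codes[j] = 0 if a == a0 else 1
            rows.append((chrom, int(pos), a0, a1, "N", False))
            call_rows.append(codes)
    if n_rejected:
        logger.info("rejected %d multi-allelic sites", n_rejected)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = (np.vstack(call_rows) if call_rows
             else np.empty((0, n), dtype=np.int8))
    return SiteMatrix(sites=sites, samples=samples, calls=calls).sort_sites()


def write_tped(matrix: SiteMatrix, tped_path, tfam_path) -> None:
    """Write the matrix back out in the transposed-text dialect."""
    with open(tfam_path, "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    a0 = matrix.sites["allele_a"].to_numpy()
    a1 = matrix.sites["allele_b"].to_numpy()
    with open(tped_path, "w") as fh:
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            toks = []
            for c in matrix.calls[i]:
                al = "0" if c < 0 else (a0[i] if c == 0 else a1[i])
                toks.append(f"{al} {al}")
            fh.write(f"{row.chrom} snp{i} 0 {row.pos} " + " ".join(toks) + "\n")


def read_site_annotations(path) -> pd.DataFrame:
    """Site-annotation TSV: chrom, pos, allele_a, allele_b, ancestral, is_cpg."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=SITE_COLUMNS, dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    df["is_cpg"] = df["is_cpg"].astype(bool)
    return df


def write_site_annotations(matrix: SiteMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SITE_COLUMNS) + "\n")
        matrix.sites[SITE_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def attach_annotations(matrix: SiteMatrix, ann: pd.DataFrame) -> SiteMatrix:
    """Merge ancestral/CpG annotations onto a matrix by (chrom, pos)."""
    merged = matrix.sites.drop(columns=["ancestral", "is_cpg"]).merge(
        ann[["chrom", "pos", "ancestral", "is_cpg"]],
        on=["chrom", "pos"], how="left",
    )
    merged["ancestral"] = merged["ancestral"].fillna("N")
    merged["is_cpg"] = merged["is_cpg"].fillna(False).astype(bool)
    out = replace(matrix)
    out.sites = merged
    return out


def read_groups(path) -> list[GroupSpec]:
    """Group table TSV with columns sample, group, role ('-' or none allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["sample", "group", "role"], dtype=str)
    groups = []
    for (name,), sub in df.groupby(["group"], sort=False):
        roles = {r for r in sub["role"].fillna("none") if r not in ("-", "")}
        roles.discard("none")
        if len(roles) > 1:
            raise ValueError(f"group {name!r} carries conflicting roles {roles}")
        role = roles.pop() if roles else "none"
        groups.append(GroupSpec(name=name, members=tuple(sub["sample"]), role=role))
    return groups


def write_groups(groups: list[GroupSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tgroup\trole\n")
        for g in groups:
            for s in g.members:
                fh.write(f"{s}\t{g.name}\t{g.role}\n")


def cpg_flags_from_reference(sites: pd.DataFrame, reference: dict[str, str]) -> np.ndarray:
    """Flag sites whose reference dinucleotide context (with the next base,
    or the previous base with the site) is CG.  1-based positions."""
    flags = np.zeros(len(sites), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        seq = reference.get(str(chrom))
        if seq is None:
            continue
        p = int(pos) - 1
        nxt = seq[p:p + 2].upper()
        prv = seq[max(p - 1, 0):p + 1].upper() if p >= 1 else ""
        flags[i] = nxt == "CG" or prv == "CG"
    return flags


# ---------------------------------------------------------------------------
# Polarization, filtering, blocking


def polarize(matrix: SiteMatrix, ancestral_track=None) -> tuple[SiteMatrix, int]:
    """Recode calls so that 0 = ancestral allele; drop unpolarizable sites.

    ``ancestral_track`` is one nucleotide (or ``N`` for unknown) per site,
    in site order; if omitted, the matrix's own ``ancestral`` annotation is
    used.  Sites whose ancestral state is unknown or matches neither allele
    are dropped.  Returns the polarized matrix and the drop count.
    """
    if ancestral_track is None:
        anc = matrix.sites["ancestral"].to_numpy(dtype=object)
    else:
        anc = np.asarray(list(ancestral_track), dtype=object)
        if len(anc) != matrix.n_sites:
            raise ValueError(
                f"ancestral track length {len(anc)} != {matrix.n_sites} sites"
            )
    a0 = matrix.sites["allele_a"].to_numpy(dtype=object)
    a1 = matrix.sites["allele_b"].to_numpy(dtype=object)
    is_a = anc == a0
    is_b = anc == a1
    keep = is_a | is_b
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("polarize: dropped %d sites with unusable ancestral state",
                    n_dropped)
    out = matrix.take_sites(keep)
    flip = is_b[keep]
    calls = out.calls.copy()
    fl = calls[flip]
    called = fl >= 0
    fl[called] = 1 - fl[called]
    calls[flip] = fl
    sites = out.sites.copy()
    sw_a = sites.loc[flip, "allele_a"].copy()
    sites.loc[flip, "allele_a"] = sites.loc[flip, "allele_b"].to_numpy()
    sites.loc[flip, "allele_b"] = sw_a.to_numpy()
    sites["ancestral"] = sites["allele_a"]
    return SiteMatrix(sites=sites, samples=out.samples, calls=calls,
                      polarized=True), n_dropped


def derived_frequencies(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and non-missing count over columns.

    Each sample contributes a single allele (pseudo-haploid semantics);
    frequency is NaN where no sample is called.
    """
    called = calls >= 0
    n_called = called.sum(axis=1)
    n_derived = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, n_derived / np.maximum(n_called, 1), np.nan)
    return freq, n_called


def filter_sites(
    matrix: SiteMatrix,
    transversions_only: bool = False,
    drop_cpg: bool = False,
    min_called: int = 0,
    min_maf: float = 0.0,
    whitelist=None,
) -> SiteMatrix:
    """Apply site filters in the order whitelist, CpG, transversion,
    min_called, MAF, logging a drop count per filter.

    MAF is the folded derived-allele frequency among non-missing haploid
    calls; ``whitelist`` is an iterable of (chrom, pos) pairs.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    out = matrix
    if whitelist is not None:
        wl = {(str(c), int(p)) for c, p in whitelist}
        keep = np.fromiter(
            ((str(c), int(p)) in wl
             for c, p in zip(out.sites["chrom"], out.sites["pos"])),
            dtype=bool, count=out.n_sites)
        logger.info("filter whitelist: dropped %d sites", int((~keep).sum()))
        out = out.take_sites(keep)
    if drop_cpg:
        keep = ~out.sites["is_cpg"].to_numpy(dtype=bool)
        logger.info("filter CpG: dropped %d sites", int((~keep).sum()))
        out = out.take_sites(keep)
    if transversions_only:
        keep = out.sites["is_transversion"].to_numpy(dtype=bool)
        logger.info("filter transversion: dropped %d sites", int((~keep).sum()))
        out = out.take_sites(keep)
    if min_called > 0:
        _, n_called = derived_frequencies(out.calls)
        keep = n_called >= min_called
        logger.info("filter min_called: dropped %d sites", int((~keep).sum()))
        out = out.take_sites(keep)
    if min_maf > 0:
        freq, n_called = derived_frequencies(out.calls)
        maf = np.minimum(freq, 1 - freq)
        keep = (n_called > 0) & (maf >= min_maf)
        logger.info("filter MAF: dropped %d sites", int((~keep).sum()))
        out = out.take_sites(keep)
    if out.n_sites == 0:
        raise ValueError("all sites removed by filters; review thresholds")
    return out


def assign_blocks(matrix: SiteMatrix, block_size: int = 5_000_000) -> BlockPartition:
    """Partition sites into contiguous genomic blocks (default 5 Mb).

    Within a chromosome the raw bin is ``floor((pos - 1) / block_size)``;
    bins are densified so only non-empty blocks carry indices.
    """
    if block_size <= 0:
        raise ValueError(f"block_size must be positive, got {block_size}")
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    bins = (pos - 1) // block_size
    keys = pd.MultiIndex.from_arrays([chroms, bins])
    codes, uniques = pd.factorize(keys, sort=True)
    return BlockPartition(
        block_size=block_size,
        block_of_site=codes.astype(np.int64),
        n_blocks=len(uniques),
        block_keys=[(str(c), int(b)) for c, b in uniques],
    )
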