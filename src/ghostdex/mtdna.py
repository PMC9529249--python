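"""N-masked pairwise differences on aligned mtDNA consensus sequences.

Consensus sequences from low-coverage ancient samples carry N at uncovered
positions; comparisons therefore skip any column where either sequence is N
(and, by default, alignment gaps).  Differences are reported as raw counts,
not per-site rates, alongside the number of compared columns, and group
summaries average the raw counts over all within-group pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclass
class MtAlignment:
    """Equal-length aligned sequences over {A, C, G, T, N, -}."""

    labels: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate sequence labels")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")

    @classmethod
    def from_fasta(cls, path) -> "MtAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls(labels=[r.id for r in recs],
                   seqs=[str(r.seq).upper() for r in recs])

    def get(self, label: str) -> str:
        return self.seqs[self.labels.index(label)]


def pairwise_differences(a: str, b: str, ignore_gaps: bool = True
                         ) -> tuple[int, int]:
    """(difference count, compared-column count) between two aligned
    sequences, masking columns where either sequence is N (or a gap,
    unless ``ignore_gaps=False``)."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    xa = np.frombuffer(a.upper().encode(), dtype="S1")
    xb = np.frombuffer(b.upper().encode(), dtype="S1")
    masked = {b"N"}
    if ignore_gaps:
        masked.add(b"-")
    ok = ~(np.isin(xa, list(masked)) | np.isin(xb, list(masked)))
    return int(((xa != xb) & ok).sum()), int(ok.sum())


def group_mean_differences(
    aln: MtAlignment,
    groups: dict[str, list[str]],
    exclusions: list[str] | None = None,
    ignore_gaps: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean within-group pairwise difference counts.

    ``exclusions`` removes labels (e.g. low-coverage consensus sequences
    called with relaxed depth) before pairing.  Groups left with fewer than
    two members are skipped with a warning.  Returns (summary, per-pair
    table); the summary mean is over raw difference counts of all unordered
    within-group pairs.
    """
    excl = set(exclusions or [])
    pair_rows, summary_rows = [], []
    for gname, members in groups.items():
        members = [m for m in members if m not in excl]
        if len(members) < 2:
            warnings.warn(f"group {gname!r} has <2 members after exclusions; "
                          "skipped", stacklevel=2)
            continue
        diffs = []
        for x, y in itertools.combinations(members, 2):
            nd, nc = pairwise_differences(aln.get(x), aln.get(y),
                                          ignore_gaps=ignore_gaps)
            pair_rows.append({"group": gname, "a": x, "b": y,
                              "differences": nd, "compared_sites": nc})
            diffs.append(nd)
        summary_rows.append({"group": gname, "n_pairs": len(diffs),
                             "mean_differences": float(np.mean(diffs))})
    return pd.DataFrame(summary_rows), pd.DataFrame(pair_rows)
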