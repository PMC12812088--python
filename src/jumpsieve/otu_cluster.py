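"""ASV -> OTU clustering at the barcoding gap.

ASVs within 3% pairwise divergence of each other are taken as one species
proxy (operational taxonomic unit). Distances are uncorrected p-distances
with pairwise deletion computed from an aligned FASTA; clustering is
agglomerative complete linkage cut so that no OTU contains a pair of ASVs
more than the cutoff apart. Tie-breaking at equal merge heights is
lexicographic so results do not depend on input order or library
internals.

The observation table is then aggregated to OTU level, and the ASV
phylogeny is collapsed to one representative tip per OTU (the most
abundant member) for phylogenetic-diversity computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode
from sklearn.base import BaseEstimator

from .errors import InputError, PreconditionError
from .obs_table import ObservationTable

# bases that count as comparable columns under pairwise deletion
_UNAMBIGUOUS = frozenset(b"ACGT")


def _load_alignment(alignment) -> tuple[list[str], np.ndarray]:
    """Accept a FASTA path or an iterable of (id, sequence) pairs."""
    if isinstance(alignment, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(alignment), "fasta")]
    else:
        records = [(i, str(s)) for i, s in alignment]
    if not records:
        raise InputError("alignment is empty")
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids in alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise InputError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    mat = np.frombuffer(
        "".join(s.upper() for _, s in records).encode(), dtype="S1"
    ).reshape(len(records), lengths.pop())
    return ids, mat


def pairwise_distances(alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an aligned FASTA (path or (id, seq) pairs).

    Uncorrected p-distance with pairwise deletion: for each pair, columns
    where either sequence carries a gap or an ambiguity code are skipped
    and the distance is mismatches / compared columns. ``model='jc69'``
    applies the Jukes-Cantor correction -3/4 ln(1 - 4p/3).
    """
    ids, mat = _load_alignment(alignment)
    valid = np.isin(mat, [bytes([b]) for b in _UNAMBIGUOUS])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            j = int(np.argmax(comparable == 0)) + i + 1
            raise InputError(
                f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
            )
        mism = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
        d[i, i + 1:] = mism / comparable
    d = d + d.T
    if model == "jc69":
        p = d
        if np.any(p >= 0.75):
            raise InputError("p-distance >= 0.75: Jukes-Cantor correction undefined")
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
    elif model != "p":
        raise InputError(f"unknown distance model {model!r}")
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Complete-linkage clustering
# ---------------------------------------------------------------------------

@dataclass
class OtuAssignment:
    """ASV -> OTU mapping with one representative ASV per OTU."""

    mapping: dict[str, str]
    representative: dict[str, str] = field(default_factory=dict)
    cutoff: float = 0.03

    @property
    def otu_ids(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, otu_id: str) -> list[str]:
        return sorted(a for a, o in self.mapping.items() if o == otu_id)

    def to_frame(self) -> pd.DataFrame:
        reps = set(self.representative.values())
        rows = [
            {"asv_id": a, "otu_id": o, "is_representative": int(a in reps)}
            for a, o in sorted(self.mapping.items())
        ]
        return pd.DataFrame(rows)


def _complete_linkage_merge(dm: DistanceMatrix, cutoff: float) -> list[list[int]]:
    """Agglomerate while the best complete-linkage distance is <= cutoff.

    Ties at equal merge height are broken by the lexicographic order of
    the candidate pair's smallest member labels, making the partition
    invariant to input order.
    """
    labels = list(dm.ids)
    d = dm.data
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    # smallest member label of each cluster, for deterministic tie-breaks
    key = [labels[i] for i in range(len(labels))]

    while len(clusters) > 1:
        best = None  # (dist, sorted label pair, index pair)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = d[np.ix_(clusters[a], clusters[b])].max()
                if dist > cutoff:
                    continue
                pair = tuple(sorted((key[a], key[b])))
                cand = (dist, pair)
                if best is None or cand < best[0]:
                    best = (cand, (a, b))
        if best is None:
            break
        a, b = best[1]
        clusters[a] = clusters[a] + clusters[b]
        key[a] = min(key[a], key[b])
        del clusters[b], key[b]
    return clusters


class CompleteLinkageOtuClusterer(BaseEstimator):
    """Complete-linkage OTU clustering at a fixed distance cutoff.

    ``fit`` takes a scikit-bio DistanceMatrix; the fitted partition is
    exposed as ``labels_`` (integer cluster index per input id, in input
    order) and ``assignment_`` (an :class:`OtuAssignment` with OTU ids
    named after the rank of each cluster's lexicographically smallest
    member).

    Parameters
    ----------
    cutoff : float
        Maximum allowed pairwise distance within an OTU (default 0.03,
        the 3% barcoding gap).
    """

    def __init__(self, cutoff: float = 0.03):
        self.cutoff = cutoff

    def fit(self, dm: DistanceMatrix, y=None) -> "CompleteLinkageOtuClusterer":
        clusters = _complete_linkage_merge(dm, self.cutoff)
        labels = list(dm.ids)
        # deterministic OTU naming: order clusters by smallest member label
        ordered = sorted(clusters, key=lambda c: min(labels[i] for i in c))
        width = max(4, len(str(len(ordered))))
        mapping: dict[str, str] = {}
        self.labels_ = np.empty(len(labels), dtype=int)
        for rank, members in enumerate(ordered):
            otu = f"OTU{rank + 1:0{width}d}"
            for i in members:
                mapping[labels[i]] = otu
                self.labels_[i] = rank
        self.assignment_ = OtuAssignment(mapping=mapping, cutoff=self.cutoff)
        return self

    def fit_predict(self, dm: DistanceMatrix, y=None) -> np.ndarray:
        return self.fit(dm).labels_


def cluster_complete_linkage(dm: DistanceMatrix, cutoff: float = 0.03) -> OtuAssignment:
    """Cluster ASVs so no OTU contains a pair farther apart than ``cutoff``."""
    return CompleteLinkageOtuClusterer(cutoff=cutoff).fit(dm).assignment_


def choose_representatives(
    assignment: OtuAssignment, table: ObservationTable
) -> OtuAssignment:
    """Pick each OTU's representative: the member with the highest total
    reads in ``table`` (absent ASVs count 0); ties go to the
    lexicographically smallest ASV id."""
    totals = table.obs.groupby("asv_id")["reads"].sum().to_dict()
    rep: dict[str, str] = {}
    for otu in assignment.otu_ids:
        members = assignment.members(otu)
        rep[otu] = min(members, key=lambda a: (-totals.get(a, 0), a))
    assignment.representative = rep
    return assignment


def aggregate_to_otus(
    table: ObservationTable, assignment: OtuAssignment
) -> pd.DataFrame:
    """Sum member-ASV reads into a sample x OTU community matrix.

    Rows cover every sample in the table's metadata (all-zero rows for
    samples with no retained observations); the grand total equals the
    table's total reads.
    """
    unmapped = sorted(set(table.obs["asv_id"]) - set(assignment.mapping))
    if unmapped:
        raise InputError(f"ASVs missing from the OTU assignment: {unmapped}")
    obs = table.obs.copy()
    obs["otu_id"] = obs["asv_id"].map(assignment.mapping)
    cm = obs.pivot_table(
        index="sample_id", columns="otu_id", values="reads", aggfunc="sum", fill_value=0
    )
    cm = cm.reindex(index=sorted(table.samples["sample_id"]), fill_value=0)
    cm = cm.reindex(columns=sorted(cm.columns)).astype(np.int64)
    cm.index.name = "sample_id"
    cm.columns.name = "otu_id"
    return cm


def collapse_tree(tree: TreeNode | str, assignment: OtuAssignment) -> TreeNode:
    """Prune the ASV tree to one representative tip per OTU, suppressing
    unbranched internals (branch lengths summed) and renaming surviving
    tips to their OTU ids. Patristic distances between representatives are
    preserved."""
    if not assignment.representative:
        raise PreconditionError("assignment has no representatives; run choose_representatives")
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    reps = {asv: otu for otu, asv in assignment.representative.items()}
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(reps) - tips)
    if missing:
        raise InputError(f"representative ASVs missing from tree: {missing}")
    if len(reps) < 2:
        raise PreconditionError(
            "fewer than two representative tips: a one-tip tree has no "
            "phylogenetic-diversity surface"
        )
    pruned = tree.shear(list(reps))
    pruned.prune()  # suppress any remaining degree-2 nodes, summing lengths
    for tip in pruned.tips():
        tip.name = reps[tip.name]
    return pruned
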