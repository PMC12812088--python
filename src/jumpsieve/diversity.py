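"""Alpha and beta diversity on the OTU community matrix.

Alpha: OTU richness and Faith's phylogenetic diversity (PD, the summed
branch length of the subtree spanning the OTUs present in a sample,
root-inclusive by default), plus a sequencing-depth correction that
replaces each index by the residual of its ordinary least-squares
regression on sample depth — a positive residual means more diversity
than the sample's depth predicts.

Beta: the Sorensen-family partition of dissimilarity into spatial
turnover (Simpson component, beta_sim) and nestedness-resultant
dissimilarity (beta_sne = beta_sor - beta_sim), pairwise and multi-site,
with a group resampling scheme (draw n sites per group without
replacement, many times) to compare groups of unequal size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InputError, PreconditionError


def to_presence_absence(cm: pd.DataFrame) -> pd.DataFrame:
    """Boolean presence/absence view of a community matrix (cell > 0)."""
    return cm > 0


def richness(cm: pd.DataFrame) -> pd.Series:
    """Number of OTUs with positive count per sample."""
    r = (cm > 0).sum(axis=1)
    r.name = "richness"
    return r


# ---------------------------------------------------------------------------
# Faith's phylogenetic diversity
# ---------------------------------------------------------------------------

def faith_pd(
    cm: pd.DataFrame, tree: TreeNode | str, include_root: bool = True
) -> pd.Series:
    """Faith's PD per sample: total branch length of the minimal subtree
    connecting the sample's present OTUs.

    With ``include_root=True`` (default, matching the common picante-style
    convention) the path from that subtree up to the tree root is
    included, so even a single-tip sample has positive PD. Samples with no
    OTUs get PD = 0.
    """
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    if len(tree.children) < 2:
        raise PreconditionError("tree must be rooted with >= 2 children at the root")
    tips = {t.name: t for t in tree.tips()}
    missing = sorted(set(cm.columns) - set(tips))
    if missing:
        raise InputError(f"OTUs missing from tree: {missing}")

    pa = cm > 0
    # fixed traversal order so the float sum is reproducible run to run
    order = list(tree.traverse(include_self=False))
    values = {}
    for sample, row in pa.iterrows():
        present = [tips[o] for o in row.index[row]]
        if not present:
            values[sample] = 0.0
            continue
        if include_root:
            anchor = tree
        else:
            anchor = present[0] if len(present) == 1 else tree.lowest_common_ancestor(present)
        edges = set()
        for tip in present:
            node = tip
            while node is not anchor and node is not None:
                edges.add(id(node))
                node = node.parent
        values[sample] = float(
            sum((n.length or 0.0) for n in order if id(n) in edges)
        )
    out = pd.Series(values).reindex(cm.index)
    out.name = "pd"
    return out


# ---------------------------------------------------------------------------
# Sequencing-depth correction
# ---------------------------------------------------------------------------

def depth_residuals(
    values: pd.Series,
    depths: pd.Series,
    zscore: bool = True,
    on_constant_depth: str = "error",
) -> pd.Series:
    """Residuals of the OLS fit ``diversity ~ depth``.

    Removes the component of a diversity index explained linearly by
    sequencing depth. ``zscore=True`` returns scaled residuals (mean 0,
    sd 1, ddof=1); otherwise raw residuals. A constant depth vector leaves
    the slope undefined: ``on_constant_depth`` is ``"error"`` (default) or
    ``"center"`` (fall back to mean-centering the diversity values).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(depths, dtype=float)
    if y.size != x.size:
        raise InputError("values and depths differ in length")
    if y.size < 3:
        raise PreconditionError("depth correction needs at least 3 samples")
    if np.any(x <= 0):
        raise InputError("sample depths must be positive")
    if np.ptp(x) == 0:
        if on_constant_depth == "center":
            resid = y - y.mean()
        else:
            raise PreconditionError(
                "constant sequencing depth: regression slope undefined "
                "(pass on_constant_depth='center' to mean-center instead)"
            )
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
    if zscore:
        sd = resid.std(ddof=1)
        resid = resid - resid.mean()
        if sd > 0:
            resid = resid / sd
    return pd.Series(resid, index=values.index, name="residual")


# ---------------------------------------------------------------------------
# Beta-diversity partitioning (Sorensen family)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPartition:
    """Total Sorensen dissimilarity and its turnover/nestedness split.

    beta_sor = beta_sim + beta_sne; all components in [0, 1].
    """

    beta_sor: float
    beta_sim: float
    beta_sne: float

    def as_dict(self) -> dict[str, float]:
        return {"beta_sor": self.beta_sor, "beta_sim": self.beta_sim,
                "beta_sne": self.beta_sne}


def beta_pairwise(pa: pd.DataFrame, i, j) -> BetaPartition:
    """Pairwise partition for samples ``i`` and ``j`` of a
    presence-absence matrix.

    With a = shared OTUs and b, c = OTUs exclusive to each sample:
    beta_sor = (b+c)/(2a+b+c); beta_sim = min(b,c)/(a+min(b,c));
    beta_sne = beta_sor - beta_sim.
    """
    if i == j:
        raise InputError("beta_pairwise needs two distinct samples")
    xi = pa.loc[i].to_numpy(dtype=bool)
    xj = pa.loc[j].to_numpy(dtype=bool)
    a = int((xi & xj).sum())
    b = int((xi & ~xj).sum())
    c = int((~xi & xj).sum())
    if a + b + c == 0:
        raise PreconditionError(f"samples {i!r} and {j!r} are both empty")
    m = min(b, c)
    sor = (b + c) / (2 * a + b + c)
    sim = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(beta_sor=sor, beta_sim=sim, beta_sne=sor - sim)


def beta_multisite(pa: pd.DataFrame) -> BetaPartition:
    """Multi-site Sorensen partition over all samples of a
    presence-absence matrix.

    With S_i the richness of site i, S_T the pooled richness and b_ij the
    number of OTUs present in i but not j (sums over unordered pairs):

        beta_SIM = sum_min / (sum_Si_minus_ST + sum_min)
        beta_SOR = (sum_min + sum_max) / (2*sum_Si_minus_ST + sum_min + sum_max)
        beta_SNE = beta_SOR - beta_SIM
    """
    x = pa.to_numpy(dtype=bool)
    if x.shape[0] < 2:
        raise PreconditionError("multi-site partition needs >= 2 samples")
    if not x.any():
        raise PreconditionError("all-empty presence-absence matrix")
    s_i = x.sum(axis=1)
    s_t = int(x.any(axis=0).sum())
    core = int(s_i.sum()) - s_t
    sum_min = 0
    sum_max = 0
    n = x.shape[0]
    for i, j in itertools.combinations(range(n), 2):
        b_ij = int((x[i] & ~x[j]).sum())
        b_ji = int((x[j] & ~x[i]).sum())
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    sim = sum_min / (core + sum_min) if (core + sum_min) > 0 else 0.0
    denom = 2 * core + sum_min + sum_max
    sor = (sum_min + sum_max) / denom if denom > 0 else 0.0
    return BetaPartition(beta_sor=sor, beta_sim=sim, beta_sne=sor - sim)


@dataclass
class ResampleDistribution:
    """Multi-site beta partitions over repeated subsamples of one group."""

    group: str
    draws: list[BetaPartition]
    n_sites: int
    n_iter: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([d.as_dict() for d in self.draws])
        df.insert(0, "group", self.group)
        return df

    def mean(self) -> dict[str, float]:
        df = self.to_frame()
        return {k: float(df[k].mean()) for k in ("beta_sor", "beta_sim", "beta_sne")}


def beta_resample(
    pa: pd.DataFrame,
    groups: pd.Series,
    n_sites: int = 20,
    n_iter: int = 1000,
    seed: int = 0,
    statistic: str = "multisite",
) -> dict[str, ResampleDistribution]:
    """Per group, draw ``n_sites`` samples without replacement ``n_iter``
    times and record the multi-site beta partition of each draw.

    Groups smaller than ``n_sites`` are resampled at their own size (with
    a warning). ``statistic='mean_pairwise'`` instead averages all
    pairwise partitions within each draw.
    """
    if statistic not in ("multisite", "mean_pairwise"):
        raise InputError(f"unknown statistic {statistic!r}")
    groups = groups.reindex(pa.index)
    out: dict[str, ResampleDistribution] = {}
    for g in sorted(groups.dropna().unique()):
        members = list(pa.index[groups == g])
        if not members:
            raise PreconditionError(f"group {g!r} is empty")
        k = n_sites
        if len(members) < n_sites:
            warnings.warn(
                f"group {g!r} has {len(members)} samples < n_sites={n_sites}; "
                f"resampling at group size", stacklevel=2
            )
            k = len(members)
        rng = np.random.default_rng([seed, _stable_hash(g)])
        draws = []
        for _ in range(n_iter):
            pick = rng.choice(len(members), size=k, replace=False)
            sub = pa.loc[[members[p] for p in sorted(pick)]]
            if statistic == "multisite":
                draws.append(beta_multisite(sub))
            else:
                parts = [
                    beta_pairwise(sub, a, b)
                    for a, b in itertools.combinations(sub.index, 2)
                ]
                draws.append(
                    BetaPartition(
                        beta_sor=float(np.mean([p.beta_sor for p in parts])),
                        beta_sim=float(np.mean([p.beta_sim for p in parts])),
                        beta_sne=float(np.mean([p.beta_sne for p in parts])),
                    )
                )
        out[g] = ResampleDistribution(
            group=str(g), draws=draws, n_sites=k, n_iter=n_iter, seed=seed
        )
    return out


def _stable_hash(label) -> int:
    """Deterministic small non-negative integer from a group label."""
    h = 0
    for ch in str(label):
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# Exclusive OTUs / Venn regions
# ---------------------------------------------------------------------------

def exclusive_otus(pa: pd.DataFrame, groups: pd.Series) -> dict:
    """Per-group exclusive OTU counts and all Venn region counts.

    An OTU belongs to a group if present in any of its samples. Returns
    ``{"exclusive": {group: count}, "regions": {"A", "A&B", ...: count}}``;
    region counts sum to the pooled richness. Capped at 6 groups.
    """
    groups = groups.reindex(pa.index)
    if groups.isna().any():
        raise InputError("every sample needs a group label for Venn counts")
    names = sorted(groups.unique())
    if len(names) > 6:
        raise InputError("Venn region counts capped at 6 groups")
    membership = {}
    for g in names:
        membership[g] = pa.loc[groups == g].any(axis=0)
    regions: dict[str, int] = {}
    per_otu = pd.DataFrame(membership)
    present = per_otu.any(axis=1)
    per_otu = per_otu.loc[present]
    for _, row in per_otu.iterrows():
        key = "&".join(g for g in names if row[g])
        regions[key] = regions.get(key, 0) + 1
    exclusive = {g: regions.get(g, 0) for g in names}
    return {"exclusive": exclusive, "regions": dict(sorted(regions.items()))}
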