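"""Synthetic metabarcoding datasets with known contamination structure.

The generator emulates the situation the blank-informed filter is built
for: a multiplexed amplicon run in which

* site-structured true communities produce an ASV x sample count table
  (lognormal species abundances, Poisson counts around a target depth),
* some index combinations are never used (blanks) and carry zero true
  reads,
* each sequenced read independently "hops" to a uniformly chosen other
  index combination (used or blank) with probability ``p_jump``,
  emulating tag-jumping / index hopping, and
* a set of spurious single-sample ASVs with small geometric read counts
  emulates point sequencing/PCR errors.

Every observation of the resulting table carries a ground-truth label
(genuine / tagjump / seqerror), so any filter can be scored for
sensitivity and specificity. A companion sequence simulator emits an
aligned FASTA and a rooted tree whose true species partition is known,
for clustering and phylogenetic-diversity tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError
from .obs_table import ObservationTable

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimParams:
    """Generative parameters for a simulated metabarcoding run.

    Defaults describe a small but realistic survey: 4 sites x 6 samples
    plus 4 blank index combinations, 150 genuine ASVs with lognormal
    abundances, ~5x10^4 reads per sample, a 2% per-read hop rate and 50
    spurious error ASVs with geometric (p=0.25) read counts.
    """

    n_sites: int = 4
    samples_per_site: int = 6
    n_blanks: int = 4
    n_species: int = 150
    mean_depth: float = 5e4
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.5
    occupancy: float = 0.6
    nested_sites: bool = False
    p_jump: float = 0.02
    n_error_asvs: int = 50
    error_read_p: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("occupancy", "p_jump", "error_read_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_sites", "samples_per_site", "n_blanks", "n_species"):
            if getattr(self, name) < 1 and name != "n_blanks":
                raise InputError(f"{name} must be positive")
        if self.n_error_asvs < 0:
            raise InputError("n_error_asvs must be >= 0")
        if self.seed is None:
            raise InputError("a seed is mandatory for stochastic simulation")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SimTruth:
    """Ground truth for a simulated table: one label per observation.

    ``labels`` has columns asv_id, sample_id, reads, label
    (genuine/tagjump/seqerror), true_reads (pre-hop genuine reads of the
    cell) and hopped_in (reads that arrived by hopping).
    """

    labels: pd.DataFrame
    params: SimParams

    def label_counts(self) -> pd.Series:
        return self.labels["label"].value_counts()


@dataclass(frozen=True)
class FilterScore:
    """Removal/retention confusion of a filter against ground truth."""

    tagjump_sensitivity: float
    genuine_specificity: float
    error_sensitivity: float
    confusion: dict

    def as_dict(self) -> dict:
        return {
            "tagjump_sensitivity": self.tagjump_sensitivity,
            "genuine_specificity": self.genuine_specificity,
            "error_sensitivity": self.error_sensitivity,
            "confusion": self.confusion,
        }


def _sample_layout(params: SimParams) -> pd.DataFrame:
    rows = []
    for s in range(params.n_sites):
        site = f"site{s + 1}"
        for k in range(params.samples_per_site):
            rows.append({"sample_id": f"{site}_r{k + 1:02d}",
                         "is_blank": False, "group": site})
    for b in range(params.n_blanks):
        rows.append({"sample_id": f"blank{b + 1:02d}", "is_blank": True,
                     "group": pd.NA})
    return pd.DataFrame(rows)


def simulate_community(params: SimParams, rng: np.random.Generator | None = None) -> ObservationTable:
    """True (error-free, pre-hop) ASV x sample count table.

    Each species occurs at each site with probability ``occupancy``
    (``nested_sites=True`` instead draws a per-site pool size and fills it
    with the first species in a fixed order, making poorer sites subsets
    of richer ones). Within a sample, expected reads are proportional to
    the species' lognormal abundance among the species present at the
    site, scaled to ``mean_depth``, and realized as Poisson counts. Blank
    samples receive zero true reads.
    """
    rng = rng or np.random.default_rng(params.seed)
    samples = _sample_layout(params)
    species = [f"asv{g + 1:04d}" for g in range(params.n_species)]
    abund = rng.lognormal(params.abundance_logmean, params.abundance_logsd,
                          size=params.n_species)

    if params.nested_sites:
        pool_sizes = rng.binomial(params.n_species, params.occupancy,
                                  size=params.n_sites)
        site_pool = {f"site{s + 1}": np.arange(params.n_species) < pool_sizes[s]
                     for s in range(params.n_sites)}
    else:
        site_pool = {
            f"site{s + 1}": rng.random(params.n_species) < params.occupancy
            for s in range(params.n_sites)
        }

    rows = []
    for _, meta in samples.iterrows():
        if meta["is_blank"]:
            continue
        present = site_pool[meta["group"]]
        if not present.any():
            continue
        w = abund * present
        expected = params.mean_depth * w / w.sum()
        counts = rng.poisson(expected)
        for g in np.nonzero(counts)[0]:
            rows.append({"asv_id": species[g], "sample_id": meta["sample_id"],
                         "reads": int(counts[g])})
    obs = pd.DataFrame(rows, columns=["asv_id", "sample_id", "reads"])
    return ObservationTable(obs, samples)


def inject_tagjumps(
    true_table: ObservationTable,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[ObservationTable, SimTruth]:
    """Hop each genuine read to a uniformly chosen other index combination
    (used or blank) with probability ``p_jump``.

    Total reads are conserved exactly. In the output truth, a cell that
    held genuine reads keeps the label ``genuine`` (even if hopped reads
    also landed there); a cell created purely by hopping is ``tagjump``.
    """
    rng = rng or np.random.default_rng(params.seed)
    samples = list(true_table.samples["sample_id"])
    idx = {s: k for k, s in enumerate(samples)}
    n = len(samples)
    if n < 2 and params.p_jump > 0:
        raise PreconditionError("hopping needs at least 2 index combinations")

    # counts[asv] = vector over samples
    genuine: dict[str, np.ndarray] = {}
    for asv, sub in true_table.obs.groupby("asv_id"):
        v = np.zeros(n, dtype=np.int64)
        v[[idx[s] for s in sub["sample_id"]]] = sub["reads"].to_numpy()
        genuine[asv] = v

    observed: dict[str, np.ndarray] = {}
    hopped_in: dict[str, np.ndarray] = {}
    remaining: dict[str, np.ndarray] = {}
    for asv, v in genuine.items():
        stay = v.copy()
        arrived = np.zeros(n, dtype=np.int64)
        if params.p_jump > 0:
            hops = rng.binomial(v, params.p_jump)
            stay = v - hops
            for origin in np.nonzero(hops)[0]:
                others = [k for k in range(n) if k != origin]
                dest = rng.multinomial(hops[origin], np.full(n - 1, 1.0 / (n - 1)))
                arrived[others] += dest
        observed[asv] = stay + arrived
        hopped_in[asv] = arrived
        remaining[asv] = stay

    rows = []
    truth_rows = []
    for asv in sorted(observed):
        obs_v = observed[asv]
        for k in np.nonzero(obs_v)[0]:
            rows.append({"asv_id": asv, "sample_id": samples[k],
                         "reads": int(obs_v[k])})
            # a cell is genuine only while it still holds reads of its own;
            # a cell fed purely by hopping is a tag-jump false positive
            label = "genuine" if remaining[asv][k] > 0 else "tagjump"
            truth_rows.append({
                "asv_id": asv, "sample_id": samples[k], "reads": int(obs_v[k]),
                "label": label, "true_reads": int(genuine[asv][k]),
                "hopped_in": int(hopped_in[asv][k]),
            })
    table = ObservationTable(
        pd.DataFrame(rows, columns=["asv_id", "sample_id", "reads"]),
        true_table.samples.copy(),
    )
    truth = SimTruth(pd.DataFrame(truth_rows), params)
    return table, truth


def inject_seq_errors(
    table: ObservationTable,
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[ObservationTable, SimTruth]:
    """Add ``n_error_asvs`` novel single-observation ASVs.

    Each error ASV lands in one index combination chosen uniformly (blanks
    included) with a shifted-geometric read count (support >= 1, mean
    1/error_read_p): most are tiny but a heavy tail exists, which is what
    gives the outlier-removal step of the read-count filter work to do.
    """
    rng = rng or np.random.default_rng(params.seed)
    if params.n_error_asvs == 0:
        return table, truth
    samples = list(table.samples["sample_id"])
    dest = rng.integers(len(samples), size=params.n_error_asvs)
    counts = rng.geometric(params.error_read_p, size=params.n_error_asvs)
    rows = []
    truth_rows = []
    for e in range(params.n_error_asvs):
        asv = f"err{e + 1:04d}"
        sample = samples[int(dest[e])]
        reads = int(counts[e])
        rows.append({"asv_id": asv, "sample_id": sample, "reads": reads})
        truth_rows.append({
            "asv_id": asv, "sample_id": sample, "reads": reads,
            "label": "seqerror", "true_reads": 0, "hopped_in": 0,
        })
    obs = pd.concat([table.obs[["asv_id", "sample_id", "reads"]],
                     pd.DataFrame(rows)], ignore_index=True)
    labels = pd.concat([truth.labels, pd.DataFrame(truth_rows)], ignore_index=True)
    return ObservationTable(obs, table.samples.copy()), SimTruth(labels, params)


# ---------------------------------------------------------------------------
# Sequence / tree simulation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return out


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def simulate_sequences(
    n_species: int,
    asvs_per_species: int = 3,
    d_within: float = 0.01,
    d_between: float = 0.08,
    length: int = 400,
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[list[tuple[str, str]], str, dict[str, str]]:
    """Aligned sequences with a known species partition, plus a rooted tree.

    Species ancestors are mutated copies of a random root sequence with
    pairwise p-distance >= ``d_between`` (verified; disjoint mutation
    blocks guarantee it when they fit in ``length``, otherwise random
    positions with bounded retries). Each ASV then receives
    floor(d_within * length / 2) private mutations, so intra-species
    p-distances never exceed ``d_within``.

    Returns (list of (asv_id, sequence), newick string, asv -> species map).
    """
    if not 0 <= d_within < d_between:
        raise InputError("need 0 <= d_within < d_between")
    rng = np.random.default_rng(seed)
    root = _BASES[rng.integers(4, size=length)]
    m_block = math.ceil(d_between * length / 2)
    k_within = math.floor(d_within * length / 2)

    if n_species * m_block <= length:
        # disjoint mutation blocks: ancestor pair distance is exactly 2*m/L
        anc_positions = [np.arange(s * m_block, (s + 1) * m_block)
                         for s in range(n_species)]
        ancestors = [_mutate(root, pos, rng) for pos in anc_positions]
        anc_branch = [m_block / length] * n_species
    else:
        m_rand = math.ceil(d_between * length)
        if m_rand > length:
            raise InputError(
                f"cannot reach d_between={d_between} at length {length}"
            )
        for _ in range(max_tries):
            ancestors = [
                _mutate(root, rng.choice(length, size=m_rand, replace=False), rng)
                for _ in range(n_species)
            ]
            ok = all(
                _p_distance(ancestors[i], ancestors[j]) >= d_between + 2 * k_within / length
                for i in range(n_species) for j in range(i + 1, n_species)
            )
            if ok:
                break
        else:
            raise InputError(
                f"could not place {n_species} ancestors at pairwise distance "
                f">= {d_between} (length {length}); increase length"
            )
        anc_branch = [_p_distance(root, a) for a in ancestors]

    records: list[tuple[str, str]] = []
    species_map: dict[str, str] = {}
    clades = []
    for s in range(n_species):
        sp = f"sp{s + 1:03d}"
        tip_strs = []
        for a in range(asvs_per_species):
            asv = f"{sp}_a{a + 1}" if asvs_per_species > 1 else sp
            if k_within > 0:
                pos = rng.choice(length, size=k_within, replace=False)
                seq = _mutate(ancestors[s], pos, rng)
            else:
                seq = ancestors[s]
            records.append((asv, seq.tobytes().decode()))
            species_map[asv] = sp
            tip_strs.append(f"{asv}:{k_within / length:.6f}")
        if asvs_per_species > 1:
            clades.append(f"({','.join(tip_strs)}):{anc_branch[s]:.6f}")
        else:
            clades.append(f"{sp}:{anc_branch[s] + k_within / length:.6f}")
    newick = f"({','.join(clades)});"

    # verify the contract on the emitted alignment
    seqs = {i: np.frombuffer(s.encode(), dtype="S1") for i, s in records}
    ids = list(seqs)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = _p_distance(seqs[ids[i]], seqs[ids[j]])
            same = species_map[ids[i]] == species_map[ids[j]]
            if same and d > d_within + 1e-12:
                raise InputError("intra-species divergence target violated")
    return records, newick, species_map


def error_asv_sequences(
    error_asv_ids: Sequence[str], length: int, seed: int
) -> list[tuple[str, str]]:
    """Independent uniform random sequences for spurious error ASVs.

    Random sequences sit at ~0.75 p-distance from everything, so they
    cluster as singleton OTUs, as real artefactual sequences typically do.
    """
    rng = np.random.default_rng(seed)
    return [
        (asv, _BASES[rng.integers(4, size=length)].tobytes().decode())
        for asv in error_asv_ids
    ]


# ---------------------------------------------------------------------------
# Whole-dataset convenience and scoring
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Observed table + ground truth + matching sequences and tree."""

    table: ObservationTable
    truth: SimTruth
    true_table: ObservationTable
    alignment: list[tuple[str, str]]
    newick: str
    species_map: dict[str, str]
    params: SimParams


def simulate_dataset(
    params: SimParams | None = None,
    with_sequences: bool = True,
    seq_length: int = 400,
    d_within: float = 0.01,
    d_between: float = 0.08,
) -> SimulatedDataset:
    """Full synthetic dataset: community -> tag-jumps -> error ASVs, plus
    an alignment and rooted tree covering every simulated ASV."""
    params = params or SimParams()
    # independent child streams per stage: changing one stage's parameters
    # never perturbs the draws of the others
    true_table = simulate_community(params, np.random.default_rng([params.seed, 1]))
    observed, truth = inject_tagjumps(
        true_table, params, np.random.default_rng([params.seed, 2]))
    observed, truth = inject_seq_errors(
        observed, truth, params, np.random.default_rng([params.seed, 3]))

    alignment: list[tuple[str, str]] = []
    newick = ""
    species_map: dict[str, str] = {}
    if with_sequences:
        seq_seed = int(np.random.default_rng([params.seed, 7]).integers(2**31 - 1))
        records, newick, species_map = simulate_sequences(
            n_species=params.n_species, asvs_per_species=1,
            d_within=d_within, d_between=d_between,
            length=seq_length, seed=seq_seed,
        )
        # align genuine ASV ids with community ASV ids (asv0001...)
        renamed = []
        rename = {}
        for k, (sp_id, seq) in enumerate(records):
            asv = f"asv{k + 1:04d}"
            renamed.append((asv, seq))
            rename[sp_id] = asv
            species_map[asv] = species_map.pop(sp_id)
        for old, new in rename.items():
            newick = newick.replace(f"{old}:", f"{new}:")
        err_ids = sorted(set(observed.obs["asv_id"]) - {a for a, _ in renamed})
        err_records = error_asv_sequences(err_ids, seq_length, seq_seed + 1)
        alignment = renamed + err_records
        if err_records:
            err_clades = ",".join(f"{a}:0.350000" for a, _ in err_records)
            newick = newick[:-2] + f",{err_clades});"
    return SimulatedDataset(
        table=observed, truth=truth, true_table=true_table,
        alignment=alignment, newick=newick, species_map=species_map,
        params=params,
    )


def score_filter(truth: SimTruth, filtered: ObservationTable) -> FilterScore:
    """Confusion of removal decisions against ground-truth labels.

    An observation counts as removed when its (asv_id, sample_id) key is
    absent from the filtered table. Sensitivities are removal fractions of
    tagjump/seqerror observations; specificity is the retained fraction of
    genuine observations.
    """
    truth_keys = set(zip(truth.labels["asv_id"], truth.labels["sample_id"]))
    kept_keys = set(zip(filtered.obs["asv_id"], filtered.obs["sample_id"]))
    stray = kept_keys - truth_keys
    if stray:
        raise InputError(
            f"filtered table contains observations absent from truth: "
            f"{sorted(stray)[:5]}"
        )
    confusion: dict[str, dict[str, int]] = {}
    for label, sub in truth.labels.groupby("label"):
        keys = set(zip(sub["asv_id"], sub["sample_id"]))
        kept = len(keys & kept_keys)
        confusion[label] = {"retained": kept, "removed": len(keys) - kept}

    def frac(label: str, which: str) -> float:
        c = confusion.get(label, {"retained": 0, "removed": 0})
        tot = c["retained"] + c["removed"]
        if tot == 0:
            return float("nan")
        return c[which] / tot

    return FilterScore(
        tagjump_sensitivity=frac("tagjump", "removed"),
        genuine_specificity=frac("genuine", "retained"),
        error_sensitivity=frac("seqerror", "removed"),
        confusion=confusion,
    )
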