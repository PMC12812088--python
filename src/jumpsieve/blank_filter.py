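"""Blank-informed two-stage filtering of tag-jumps and sequencing errors.

Index hopping (tag-jumping) moves sequenced fragments between index
combinations, creating false-positive observations. Index combinations
that were never used in an experiment ("blank samples") should carry zero
reads, so every observation they do carry is a known error. Those known
errors calibrate two data-driven filters:

Filter 1, "sequencing errors": ASVs found in exactly one sample, that
sample being a blank, cannot be tag-jumps (a jump implies a source sample
also containing the ASV). Their read counts are the known magnitude of
point sequencing/PCR artefacts. After discarding high outliers by Tukey's
boxplot rule, the maximum remaining count becomes the read-count cutoff
``t_reads``; observations at or below it are removed.

Filter 2, "tag jump": on the blank observations that survive filter 1,
the high outliers of the ``readprop`` and ``norm`` distributions mark
where blank (erroneous) observations stop looking like ordinary hopped
read packets. The minimum of each outlier set becomes a threshold, and a
real-sample observation is retained iff it beats at least one of them:
``readprop > t_readprop OR norm > t_norm``.

All three cutoffs carry full provenance (the exact value multiset, hinges,
fence and outlier set used), so a derivation can be replayed and audited.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import PreconditionError
from .obs_table import ObservationTable, compute_stats

logger = logging.getLogger(__name__)

Scope = Literal["blanks", "nonblanks", "all"]


# ---------------------------------------------------------------------------
# Tukey boxplot outliers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierSplit:
    """A multiset of values split at the upper Tukey fence.

    ``outliers`` lie strictly above ``upper_fence``; ``body`` is the rest.
    Hinges follow the five-number-summary convention (hinge depth
    ``(floor((n+1)/2) + 1) / 2``, averaging the two flanking order
    statistics when the depth is fractional), the same convention as R's
    ``boxplot.stats``/``fivenum``.
    """

    outliers: np.ndarray
    body: np.ndarray
    lower_hinge: float
    upper_hinge: float
    upper_fence: float


def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Lower and upper Tukey hinges of a non-empty 1-d array."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    depth = (np.floor((n + 1) / 2) + 1) / 2  # hinge depth, possibly *.5
    lo_idx = int(np.floor(depth)) - 1, int(np.ceil(depth)) - 1
    lower = (x[lo_idx[0]] + x[lo_idx[1]]) / 2
    upper = (x[n - 1 - lo_idx[0]] + x[n - 1 - lo_idx[1]]) / 2
    return float(lower), float(upper)


def tukey_outliers(values, coef: float = 1.5) -> OutlierSplit:
    """Split values at the upper Tukey fence (upper hinge + coef * H-spread).

    Only the high side is considered: the filters look for erroneous
    observations that are unusually *large*, and the derived thresholds
    are minima of high-side outlier sets.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise PreconditionError("tukey_outliers requires a non-empty multiset")
    lower, upper = tukey_hinges(x)
    fence = upper + coef * (upper - lower)
    mask = x > fence
    return OutlierSplit(
        outliers=np.sort(x[mask]),
        body=np.sort(x[~mask]),
        lower_hinge=lower,
        upper_hinge=upper,
        upper_fence=float(fence),
    )


def _split_record(split: OutlierSplit, values) -> dict:
    return {
        "values": [float(v) for v in values],
        "lower_hinge": split.lower_hinge,
        "upper_hinge": split.upper_hinge,
        "upper_fence": split.upper_fence,
        "outliers": [float(v) for v in split.outliers],
        "body": [float(v) for v in split.body],
    }


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass
class FilterThresholds:
    """The three blank-derived cutoffs plus their derivation provenance.

    ``provenance`` maps each derivation step (``seq_error``, ``readprop``,
    ``norm``) to the value multiset, hinges, fence and outlier set used;
    :func:`replay_provenance` recomputes the thresholds from it.
    """

    t_reads: int
    t_readprop: float
    t_norm: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "FilterThresholds":
        d = json.loads(text)
        return cls(**d)


def replay_provenance(thresholds: FilterThresholds) -> tuple[int, float, float]:
    """Re-derive (t_reads, t_readprop, t_norm) from stored provenance.

    Returns the replayed triple; agreement with the stored thresholds is
    the audit criterion.
    """
    prov = thresholds.provenance
    se = tukey_outliers(prov["seq_error"]["values"])
    t_reads = int(max(se.body))
    rp = tukey_outliers(prov["readprop"]["values"])
    t_readprop = float(min(rp.outliers))
    nm = tukey_outliers(prov["norm"]["values"])
    t_norm = float(min(nm.outliers))
    return t_reads, t_readprop, t_norm


def derive_seq_error_threshold(
    table: ObservationTable, min_blank_errors: int = 5
) -> tuple[int, dict]:
    """Filter-1 cutoff: max read count of blank-only singleton ASVs after
    outlier removal.

    Qualifying observations are those whose ASV occurs in exactly one
    sample (readprop = 1) and that sample is a blank — errors that cannot
    be tag-jumps. Returns (t_reads, provenance record).
    """
    if not table.has_stats:
        raise PreconditionError("compute_stats must run before threshold derivation")
    if not table.blank_sample_ids:
        raise PreconditionError(
            "no blank samples in metadata; blank-informed thresholds cannot be derived"
        )
    obs = table.obs
    singleton = obs.groupby("asv_id")["sample_id"].transform("size") == 1
    qualifying = obs.loc[singleton & table.is_blank_obs(), "reads"]
    if len(qualifying) < min_blank_errors:
        raise PreconditionError(
            f"only {len(qualifying)} blank-only singleton observations "
            f"(need >= {min_blank_errors}); derive the read-count threshold manually"
        )
    split = tukey_outliers(qualifying.to_numpy())
    t_reads = int(max(split.body))
    prov = _split_record(split, qualifying)
    prov["n_qualifying"] = int(len(qualifying))
    prov["t_reads"] = t_reads
    logger.info(
        "sequencing-error threshold: %d qualifying blank singletons, "
        "hinges (%.6g, %.6g), fence %.6g, %d outliers removed, t_reads = %d",
        len(qualifying), split.lower_hinge, split.upper_hinge,
        split.upper_fence, split.outliers.size, t_reads,
    )
    return t_reads, prov


def apply_seq_error_filter(
    table: ObservationTable,
    t_reads: int,
    scope: Scope = "all",
    strict: bool = False,
) -> ObservationTable:
    """Remove low-read observations within ``scope``.

    Default comparison is inclusive (reads <= t_reads removed): the cutoff
    is the maximum of known errors, so counts equal to it are still
    presumed errors. ``strict=True`` removes only reads < t_reads.
    """
    in_scope = _scope_mask(table, scope)
    reads = table.obs["reads"]
    low = reads < t_reads if strict else reads <= t_reads
    return table.subset(~(in_scope & low))


def derive_tagjump_thresholds(
    table: ObservationTable,
    t_reads: int,
    min_blank_errors: int = 5,
    filter1_strict: bool = False,
) -> tuple[float, float, dict, dict]:
    """Filter-2 cutoffs from blank observations surviving filter 1.

    On the post-filter-1 blank observations, t_readprop is the minimum of
    the high outliers of the readprop distribution and t_norm the minimum
    of the high outliers of the norm distribution. Both outlier sets must
    be non-empty: without outliers the data-driven rule is undefined and a
    manual threshold is required.
    """
    if not table.has_stats:
        raise PreconditionError("compute_stats must run before threshold derivation")
    blanks_f1 = apply_seq_error_filter(table, t_reads, scope="blanks", strict=filter1_strict)
    blank_obs = blanks_f1.obs[blanks_f1.is_blank_obs()]
    if len(blank_obs) < min_blank_errors:
        raise PreconditionError(
            f"only {len(blank_obs)} blank observations survive filter 1 "
            f"(need >= {min_blank_errors})"
        )
    out = []
    for col in ("readprop", "norm"):
        split = tukey_outliers(blank_obs[col].to_numpy())
        if split.outliers.size == 0:
            raise PreconditionError(
                f"no high outliers in blank {col} values; the data-driven "
                f"threshold is undefined — supply a manual threshold"
            )
        thr = float(min(split.outliers))
        prov = _split_record(split, blank_obs[col])
        prov["threshold"] = thr
        logger.info(
            "tag-jump %s threshold: %d blank observations, hinges (%.6g, %.6g), "
            "fence %.6g, %d outliers, threshold = %.9g",
            col, len(blank_obs), split.lower_hinge, split.upper_hinge,
            split.upper_fence, split.outliers.size, thr,
        )
        out.append((thr, prov))
    (t_readprop, prov_rp), (t_norm, prov_nm) = out
    return t_readprop, t_norm, prov_rp, prov_nm


def apply_tagjump_filter(
    table: ObservationTable,
    t_readprop: float,
    t_norm: float,
    scope: Scope = "nonblanks",
) -> ObservationTable:
    """Retain an in-scope observation iff readprop > t_readprop OR
    norm > t_norm (strict comparisons, disjunctive)."""
    if not table.has_stats:
        raise PreconditionError("observations lack readprop/norm statistics")
    in_scope = _scope_mask(table, scope)
    passes = (table.obs["readprop"] > t_readprop) | (table.obs["norm"] > t_norm)
    return table.subset(~in_scope | passes)


def _scope_mask(table: ObservationTable, scope: Scope) -> pd.Series:
    if scope == "all":
        return pd.Series(True, index=table.obs.index)
    blank = table.is_blank_obs()
    if scope == "blanks":
        return blank
    if scope == "nonblanks":
        return ~blank
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Full two-stage filter
# ---------------------------------------------------------------------------

class BlankFilter(BaseEstimator):
    """Two-stage blank-informed decontamination filter.

    ``fit`` computes per-observation statistics and derives the three
    thresholds from the table's blank samples; ``transform`` applies the
    sequencing-error filter then the conditional tag-jump filter to the
    non-blank samples and drops the blanks from the output.

    Parameters
    ----------
    min_blank_errors : int
        Minimum qualifying blank observations for each derivation step.
    filter1_strict : bool
        If True, filter 1 removes only reads strictly below t_reads
        (default False: counts equal to the cutoff are also removed).
    recompute_stats_after_filter1 : bool
        If True, readprop/exprop/norm are recomputed after filter 1 has
        been applied to the whole table, before deriving and applying the
        tag-jump thresholds. Default False: statistics are computed once on
        the raw table.

    Attributes
    ----------
    thresholds_ : FilterThresholds
        Derived cutoffs with provenance.
    report_ : list of dict
        Observation/read/ASV counts after every pipeline step.
    """

    def __init__(
        self,
        min_blank_errors: int = 5,
        filter1_strict: bool = False,
        recompute_stats_after_filter1: bool = False,
    ):
        self.min_blank_errors = min_blank_errors
        self.filter1_strict = filter1_strict
        self.recompute_stats_after_filter1 = recompute_stats_after_filter1

    # sklearn's y is meaningless here; accepted for pipeline compatibility
    def fit(self, table: ObservationTable, y=None) -> "BlankFilter":
        stats = compute_stats(table)
        t_reads, prov_se = derive_seq_error_threshold(stats, self.min_blank_errors)
        if self.recompute_stats_after_filter1:
            basis = compute_stats(
                apply_seq_error_filter(stats, t_reads, "all", self.filter1_strict)
            )
        else:
            basis = stats
        t_rp, t_nm, prov_rp, prov_nm = derive_tagjump_thresholds(
            basis, t_reads, self.min_blank_errors, self.filter1_strict
        )
        self.thresholds_ = FilterThresholds(
            t_reads=t_reads,
            t_readprop=t_rp,
            t_norm=t_nm,
            provenance={"seq_error": prov_se, "readprop": prov_rp, "norm": prov_nm},
        )
        self._stats_table_ = stats
        return self

    def transform(self, table: ObservationTable) -> ObservationTable:
        if not hasattr(self, "thresholds_"):
            raise PreconditionError("BlankFilter.transform called before fit")
        thr = self.thresholds_
        report: list[dict] = []

        stats = table if table.has_stats else compute_stats(table)
        _log_step(report, "input", stats)

        blanks_f1 = apply_seq_error_filter(
            stats, thr.t_reads, "blanks", self.filter1_strict
        )
        _log_step(report, "filter1_blanks", blanks_f1)

        if self.recompute_stats_after_filter1:
            work = compute_stats(
                apply_seq_error_filter(blanks_f1, thr.t_reads, "nonblanks", self.filter1_strict)
            )
            _log_step(report, "filter1_nonblanks", work)
        else:
            work = apply_seq_error_filter(
                blanks_f1, thr.t_reads, "nonblanks", self.filter1_strict
            )
            _log_step(report, "filter1_nonblanks", work)

        work = apply_tagjump_filter(work, thr.t_readprop, thr.t_norm, "nonblanks")
        _log_step(report, "filter2_nonblanks", work)

        work = work.drop_samples(work.blank_sample_ids)
        _log_step(report, "drop_blanks", work)

        self.report_ = report
        return work

    def fit_transform(self, table: ObservationTable, y=None) -> ObservationTable:
        return self.fit(table).transform(table)


def _log_step(report: list, step: str, table: ObservationTable) -> None:
    entry = {
        "step": step,
        "n_obs": table.n_obs,
        "n_reads": table.total_reads,
        "n_asvs": int(table.obs["asv_id"].nunique()),
    }
    report.append(entry)
    logger.info("%s: %d observations, %d reads, %d ASVs",
                step, entry["n_obs"], entry["n_reads"], entry["n_asvs"])


def run_blank_filter(
    table: ObservationTable,
    min_blank_errors: int = 5,
    filter1_strict: bool = False,
    recompute_stats_after_filter1: bool = False,
) -> tuple[ObservationTable, FilterThresholds, list[dict]]:
    """Derive thresholds and run the full two-stage filter.

    Returns (filtered table with blanks dropped, thresholds, per-step report).
    """
    bf = BlankFilter(
        min_blank_errors=min_blank_errors,
        filter1_strict=filter1_strict,
        recompute_stats_after_filter1=recompute_stats_after_filter1,
    )
    filtered = bf.fit_transform(table)
    return filtered, bf.thresholds_, bf.report_
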