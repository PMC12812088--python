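"""Observation tables for metabarcoding count data.

A metabarcoding run yields a sparse ASV-by-sample matrix of read counts.
This module stores it in long form — one row per *observation*, i.e. one
(ASV, sample) cell with a positive count — together with per-sample
metadata flagging which index combinations are blanks (combinations never
used in the experiment, so any reads they carry are known errors).

Three per-observation statistics drive the blank-informed filtering:

``readprop``
    reads of the observation divided by the total reads of that ASV over
    the whole table (blanks included).
``exprop``
    the readprop expected if the ASV's reads were spread evenly over its
    observations: 1 / (number of observations of that ASV).
``norm``
    (readprop - exprop) / exprop, a relative divergence from the even
    spread; it is -1 when an observation holds a vanishing share of the
    ASV's reads (the signature of a small hopped read packet) and 0 when
    the observation holds exactly its even share.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError

OBS_COLUMNS = ["asv_id", "sample_id", "reads"]
STAT_COLUMNS = ["readprop", "exprop", "norm"]


def _default_sample_meta(sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = pd.Index(sorted(set(sample_ids)), name=None)
    return pd.DataFrame(
        {"sample_id": ids, "is_blank": False, "group": pd.NA}
    ).reset_index(drop=True)


@dataclass
class ObservationTable:
    """Long-form (ASV, sample, reads) records plus sample metadata.

    Parameters
    ----------
    obs : pandas.DataFrame
        Columns ``asv_id``, ``sample_id``, ``reads`` (positive integers);
        after :func:`compute_stats` also ``readprop``, ``exprop``, ``norm``.
    samples : pandas.DataFrame
        Columns ``sample_id``, ``is_blank`` (bool), ``group`` (optional
        label). Every sample referenced by an observation must appear here.
    """

    obs: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        obs = self.obs.copy()
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise InputError(f"observation table lacks columns {missing}")
        if not np.issubdtype(np.asarray(obs["reads"]).dtype, np.number):
            raise InputError("read counts must be numeric")
        reads = obs["reads"].to_numpy()
        if np.any(reads != np.floor(reads)):
            raise InputError("read counts must be integers")
        obs["reads"] = obs["reads"].astype(np.int64)
        if (obs["reads"] < 0).any():
            bad = obs.loc[obs["reads"] < 0, OBS_COLUMNS].head()
            raise InputError(f"negative read counts:\n{bad}")
        obs = obs[obs["reads"] > 0].reset_index(drop=True)
        dup = obs.duplicated(subset=["asv_id", "sample_id"])
        if dup.any():
            key = tuple(obs.loc[dup.idxmax(), ["asv_id", "sample_id"]])
            raise InputError(f"duplicate (asv_id, sample_id) key: {key}")
        self.obs = obs

        if self.samples is None:
            self.samples = _default_sample_meta(obs["sample_id"])
        else:
            samples = self.samples.copy()
            if "sample_id" not in samples.columns:
                raise InputError("sample metadata lacks a sample_id column")
            if samples["sample_id"].duplicated().any():
                raise InputError("duplicate sample_id in metadata")
            if "is_blank" not in samples.columns:
                samples["is_blank"] = False
            samples["is_blank"] = samples["is_blank"].map(_parse_bool)
            if "group" not in samples.columns:
                samples["group"] = pd.NA
            unknown = set(obs["sample_id"]) - set(samples["sample_id"])
            if unknown:
                raise InputError(
                    f"observations reference samples absent from metadata: {sorted(unknown)}"
                )
            self.samples = samples.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def has_stats(self) -> bool:
        return all(c in self.obs.columns for c in STAT_COLUMNS)

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    @property
    def total_reads(self) -> int:
        return int(self.obs["reads"].sum())

    @property
    def asv_ids(self) -> list[str]:
        return sorted(self.obs["asv_id"].unique())

    @property
    def blank_sample_ids(self) -> list[str]:
        s = self.samples
        return sorted(s.loc[s["is_blank"], "sample_id"])

    def sample_depths(self, include_absent: bool = True) -> pd.Series:
        """Total reads per sample; samples with no observations get 0."""
        depths = self.obs.groupby("sample_id")["reads"].sum()
        if include_absent:
            depths = depths.reindex(self.samples["sample_id"], fill_value=0)
        depths.name = "depth"
        return depths.astype(np.int64)

    def is_blank_obs(self) -> pd.Series:
        """Boolean mask over obs rows: observation lies in a blank sample."""
        blanks = set(self.blank_sample_ids)
        return self.obs["sample_id"].isin(blanks)

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.obs.copy(), self.samples.copy())

    def subset(self, mask: pd.Series) -> "ObservationTable":
        """New table keeping obs rows where mask is True; metadata unchanged."""
        return ObservationTable(
            self.obs[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            self.samples.copy(),
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "ObservationTable":
        drop = set(sample_ids)
        obs = self.obs[~self.obs["sample_id"].isin(drop)].reset_index(drop=True)
        samples = self.samples[~self.samples["sample_id"].isin(drop)].reset_index(
            drop=True
        )
        return ObservationTable(obs, samples)

    def to_wide(self) -> pd.DataFrame:
        """Dense ASV x sample count matrix (zeros for absent cells)."""
        wide = self.obs.pivot(index="asv_id", columns="sample_id", values="reads")
        return wide.fillna(0).astype(np.int64)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise InputError(f"cannot interpret is_blank value {x!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path | io.TextIOBase,
    layout: Literal["long", "wide"] = "long",
    samples: str | Path | pd.DataFrame | None = None,
    sep: str = "\t",
) -> ObservationTable:
    """Read an observation table from TSV.

    ``long`` layout expects columns ``asv_id  sample_id  reads``; ``wide``
    layout expects a first column ``asv_id`` and one count column per
    sample (zero cells are dropped on melt). ``samples`` is an optional
    metadata table (path or DataFrame) with ``sample_id  is_blank  group``;
    when omitted every sample defaults to non-blank.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read observation table: {exc}") from exc

    if layout == "long":
        missing = [c for c in OBS_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"long table lacks columns {missing}")
        obs = df[OBS_COLUMNS]
    elif layout == "wide":
        if df.columns[0] != "asv_id":
            raise InputError("wide table must have 'asv_id' as its first column")
        obs = df.melt(id_vars="asv_id", var_name="sample_id", value_name="reads")
        obs = obs[obs["reads"] != 0]
    else:
        raise InputError(f"unknown layout {layout!r}")

    if not np.issubdtype(np.asarray(obs["reads"]).dtype, np.number):
        raise InputError("non-numeric read counts in table")

    meta = None
    if samples is not None:
        meta = samples if isinstance(samples, pd.DataFrame) else pd.read_csv(samples, sep=sep)
    return ObservationTable(obs.reset_index(drop=True), meta)


def write_table(table: ObservationTable, path: str | Path, sep: str = "\t") -> None:
    """Write the long-form observation table (including any statistics)."""
    table.obs.to_csv(path, sep=sep, index=False)


def write_sample_meta(table: ObservationTable, path: str | Path, sep: str = "\t") -> None:
    out = table.samples.copy()
    out["is_blank"] = out["is_blank"].astype(int)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Statistics and taxonomy filter
# ---------------------------------------------------------------------------

def compute_stats(table: ObservationTable) -> ObservationTable:
    """Attach readprop, exprop and norm to every observation.

    Statistics are computed on the table as given: the readprop denominator
    is the ASV's total reads over *all* samples, blanks included, because
    the filter thresholds are themselves derived from blank observations of
    this same table. The operation is idempotent.
    """
    if table.n_obs == 0:
        raise PreconditionError("cannot compute statistics on an empty table")
    obs = table.obs.copy()
    grp = obs.groupby("asv_id")["reads"]
    total = grp.transform("sum").to_numpy(dtype=float)
    n_occ = grp.transform("size").to_numpy(dtype=float)
    readprop = obs["reads"].to_numpy(dtype=float) / total
    exprop = 1.0 / n_occ
    obs["readprop"] = readprop
    obs["exprop"] = exprop
    obs["norm"] = (readprop - exprop) / exprop
    return ObservationTable(obs, table.samples.copy())


def read_taxonomy(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-ASV taxonomy table: ``asv_id  taxon  identity_pct``."""
    tax = pd.read_csv(path, sep=sep)
    missing = [c for c in ("asv_id", "identity_pct") if c not in tax.columns]
    if missing:
        raise InputError(f"taxonomy table lacks columns {missing}")
    if tax["asv_id"].duplicated().any():
        raise InputError("duplicate asv_id in taxonomy table")
    ident = tax["identity_pct"].to_numpy(dtype=float)
    if np.any((ident < 0) | (ident > 100)):
        raise InputError("identity_pct must lie in [0, 100]")
    return tax


def filter_by_identity(
    table: ObservationTable,
    taxonomy: pd.DataFrame,
    min_identity: float = 84.0,
    missing_policy: Literal["error", "drop", "keep"] = "error",
) -> ObservationTable:
    """Drop all observations of ASVs whose taxonomic identity is below
    ``min_identity`` percent (strictly below: an ASV at exactly the
    threshold is kept).

    ``missing_policy`` governs ASVs absent from the taxonomy table:
    ``error`` (default) raises listing them, ``drop`` removes them,
    ``keep`` retains them.
    """
    ident = dict(zip(taxonomy["asv_id"], taxonomy["identity_pct"].astype(float)))
    asvs = table.obs["asv_id"]
    missing = sorted(set(asvs) - set(ident))
    if missing and missing_policy == "error":
        raise InputError(f"ASVs missing from taxonomy table: {missing}")
    keep_missing = missing_policy == "keep"

    def keep(asv: str) -> bool:
        if asv not in ident:
            return keep_missing
        return ident[asv] >= min_identity

    mask = asvs.map(keep)
    return table.subset(mask)
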