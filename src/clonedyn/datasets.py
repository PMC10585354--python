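"""Clonal tracking tables: reading, validation, and preprocessing.

The canonical container is a long (tidy) table with one row per recaptured
(clone, time, lineage) cell count.  The absence of a row *is* the datum "not
recaptured": undetected entries are unmeasured states, never zeros.  Zero
counts in input files are therefore dropped to missing by default (a dialect
flag keeps them as observations of zero for assays where that is the right
reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kalman import CloneObservations
from .network import DifferentiationNetwork

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("clone_id", "time", "lineage", "count")


class DatasetError(ValueError):
    """Raised for malformed clonal tracking tables."""


@dataclass
class ClonalTrackingDataset:
    """Long-format clonal tracking table with per-clone selection structure."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["clone_id"] = df["clone_id"].astype(str)
        df["lineage"] = df["lineage"].astype(str)
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
        df["count"] = pd.to_numeric(df["count"], errors="raise").astype(float)
        if not np.all(np.isfinite(df["time"])) or not np.all(np.isfinite(df["count"])):
            raise DatasetError("non-finite time or count values")
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0].iloc[0]
            raise DatasetError(f"negative count for {tuple(bad[:3])}")
        dup = df.duplicated(subset=["clone_id", "time", "lineage"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise DatasetError(
                f"duplicate (clone, time, lineage) triple "
                f"({bad['clone_id']}, {bad['time']}, {bad['lineage']})")
        self.frame = df.sort_values(
            ["clone_id", "time", "lineage"]).reset_index(drop=True)

    # -- queries ----------------------------------------------------------

    @property
    def clones(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["clone_id"].unique()))

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["lineage"].unique()))

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def observation_sequences(self, net: DifferentiationNetwork,
                              ) -> dict[str, CloneObservations]:
        """Per-clone measurement records aligned to a network's state order.

        Each present (time, lineage) row yields one selection row in that
        time's ``G_k``.  Lineage names must be network nodes.
        """
        unknown = set(self.frame["lineage"]) - set(net.nodes)
        if unknown:
            raise DatasetError(f"lineages not in network: {sorted(unknown)}")
        node_pos = {x: i for i, x in enumerate(net.nodes)}
        out: dict[str, CloneObservations] = {}
        for clone, cdf in self.frame.groupby("clone_id", sort=True):
            times = np.sort(cdf["time"].unique())
            Gs, ys = [], []
            for t in times:
                rows = cdf[cdf["time"] == t].sort_values("lineage")
                idx = [node_pos[x] for x in rows["lineage"]]
                G = np.zeros((len(idx), net.n))
                G[np.arange(len(idx)), idx] = 1.0
                Gs.append(G)
                ys.append(rows["count"].to_numpy(dtype=float))
            out[str(clone)] = CloneObservations(
                clone_id=str(clone), times=times, G=tuple(Gs), y=tuple(ys))
        return out

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_wide(self) -> pd.DataFrame:
        """Pivot to (clone, time) x lineage; missing entries become NaN."""
        return self.frame.pivot_table(index=["clone_id", "time"],
                                      columns="lineage", values="count",
                                      aggfunc="first")


def read_dataset(path, *, column_map: Mapping[str, str] | None = None,
                 zeros_are_observations: bool = False,
                 sep: str = ",") -> ClonalTrackingDataset:
    """Read a long-format delimited table into a validated dataset.

    ``column_map`` renames input columns onto the canonical four
    (``clone_id, time, lineage, count``).  With the default dialect, zero
    counts are dropped to missing (they are treated as recapture failures);
    set ``zeros_are_observations=True`` to keep them as measured zeros.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    if not zeros_are_observations:
        n_zero = int((df["count"] == 0).sum())
        if n_zero:
            logger.info("%s: dropped %d zero-count rows to MISSING "
                        "(zeros_are_observations=False)", path, n_zero)
            df = df[df["count"] != 0]
    return ClonalTrackingDataset(df.reset_index(drop=True),
                                 metadata={"source": str(path),
                                           "zeros_are_observations": zeros_are_observations})


def from_wide(df: pd.DataFrame, *, zeros_are_observations: bool = False,
              ) -> ClonalTrackingDataset:
    """Melt a (clone_id, time) x lineage wide table into the long canon."""
    long = df.reset_index().melt(id_vars=["clone_id", "time"],
                                 var_name="lineage", value_name="count")
    long = long.dropna(subset=["count"])
    if not zeros_are_observations:
        long = long[long["count"] != 0]
    return ClonalTrackingDataset(long.reset_index(drop=True))


def top_recaptured_clones(ds: ClonalTrackingDataset, n: int) -> ClonalTrackingDataset:
    """Keep the n clones with the most present (time, lineage) records.

    Ties at the cutoff are broken by lexicographically smaller clone id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = ds.frame.groupby("clone_id").size()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    keep = set(order[:n])
    sub = ds.frame[ds.frame["clone_id"].isin(keep)]
    meta = dict(ds.metadata)
    meta["top_recaptured"] = int(n)
    return ClonalTrackingDataset(sub.reset_index(drop=True), metadata=meta)


def rescale_by_sample(ds: ClonalTrackingDataset,
                      factors: Mapping) -> ClonalTrackingDataset:
    """Multiply counts by per-sample factors.

    ``factors`` is keyed either by time (one factor per sampling time) or by
    ``(time, lineage)`` pairs.  This is the generic hook for study-specific
    normalisations (library size, DNA amount); no particular published
    rescaling recipe is implied.
    """
    df = ds.frame.copy()
    fac = np.ones(len(df))
    for key, f in factors.items():
        f = float(f)
        if f <= 0:
            raise ValueError(f"factor for {key!r} must be positive")
        if isinstance(key, tuple):
            t, lin = key
            mask = (df["time"] == float(t)) & (df["lineage"] == str(lin))
        else:
            mask = df["time"] == float(key)
        if not mask.any():
            raise ValueError(f"factor key {key!r} matches no records")
        fac[mask.to_numpy()] = f
    df["count"] = df["count"] * fac
    meta = dict(ds.metadata)
    meta["rescaled"] = {str(k): float(v) for k, v in factors.items()}
    return ClonalTrackingDataset(df, metadata=meta)


def library_size_factors(ds: ClonalTrackingDataset) -> dict[float, float]:
    """Per-time sum-normalisation factors to the median sample depth."""
    totals = ds.frame.groupby("time")["count"].sum()
    med = float(totals.median())
    return {float(t): med / float(s) for t, s in totals.items()}
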