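"""SASV identification and shared-fraction depth profiles.

A SASV ("shared ASV") is an amplicon sequence variant found both suspended in
the water column and in sinking particles collected by a sediment trap, with
*exactly identical* sequences in the two compartments. For the moored-trap
time series, each trap collection interval is compared against a monthly
climatology of the water column — the per-calendar-month mean of the
water-column relative-abundance vectors at every sampled depth, averaged
across years. For expedition-style deployments where water samples are
contemporaneous with the traps, a "direct" reference pools the same-period
water samples per depth instead (``direct_reference``).

Two directions of the shared-fraction statistic are computed per (trap
interval, water depth) pair:

* ``water_fraction`` — summed *water-column* relative abundance of the shared
  set: how much of the suspended community at depth Z is entrained in
  particles reaching the trap;
* ``trap_fraction`` — summed *trap* relative abundance of the shared set: how
  much of the trap community originates from (is also found at) depth Z. An
  ASV found at several depths contributes its full trap abundance at each, so
  these fractions may sum to more than one across depths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import AbundanceMatrix, AsvRecord, SampleRecord

logger = logging.getLogger("sasvtrace")

#: Pseudo-month key used by the direct (climatology-free) reference mode.
DIRECT_MONTH = 0


@dataclass
class MonthlyClimatology:
    """Mapping (depth_m, month) -> mean water-column relative-abundance vector.

    ``n_years`` records how many years contributed to each entry;
    ``interpolated`` flags entries filled from calendar-adjacent months.
    """

    data: dict[tuple[float, int], pd.Series]
    n_years: dict[tuple[float, int], int] = field(default_factory=dict)
    interpolated: set[tuple[float, int]] = field(default_factory=set)

    def vector(self, depth_m: float, month: int) -> pd.Series:
        key = (float(depth_m), int(month))
        if key not in self.data:
            raise KeyError(
                f"no climatology entry for depth {depth_m} m, month {month}")
        return self.data[key]

    @property
    def depths(self) -> list[float]:
        return sorted({d for d, _ in self.data})

    def months_at(self, depth_m: float) -> list[int]:
        return sorted({m for d, m in self.data if d == float(depth_m)})

    def validate(self, tol: float = 1e-9) -> None:
        for key, vec in self.data.items():
            s = float(vec.sum())
            if abs(s - 1.0) > tol:
                raise ValueError(
                    f"climatology vector at {key} sums to {s}, not 1 ± {tol}")


@dataclass(frozen=True)
class SasvSet:
    """Shared ASVs between one trap sample and one water depth/month.

    ``water_asv_ids`` / ``trap_asv_ids`` hold the matched ids on each side of
    the comparison (identical unless the two compartments use distinct id
    namespaces for the same sequence); ``asv_ids`` is their union.
    """

    trap_sample_id: str
    water_depth_m: float
    month: int
    water_asv_ids: frozenset[str]
    trap_asv_ids: frozenset[str]

    @property
    def asv_ids(self) -> frozenset[str]:
        return self.water_asv_ids | self.trap_asv_ids


@dataclass
class DepthProfileStat:
    """Per-depth mean, sample standard deviation and n of a fraction."""

    table: pd.DataFrame  # columns: depth_m, mean, sd, n

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["mean"] >= -1e-12) & (t["mean"] <= 1 + 1e-9)).all():
            raise ValueError("profile means must lie in [0, 1]")
        if (t["sd"] < 0).any() or (t["n"] < 1).any():
            raise ValueError("sd must be >= 0 and n >= 1")

    def to_frame(self) -> pd.DataFrame:
        return self.table[["depth_m", "mean", "sd", "n"]].copy()

    @property
    def depths(self) -> np.ndarray:
        return self.table["depth_m"].to_numpy(dtype=float)

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# climatology


def monthly_climatology(
    water: AbundanceMatrix, samples: Sequence[SampleRecord]
) -> MonthlyClimatology:
    """Per-(depth, calendar month) mean of water-column relative abundances.

    Replicates at one depth and date are averaged first, then dates within one
    (year, month), then the per-year vectors are averaged unweighted across
    years — e.g. the March mean at 5 m with two sampled years is the plain
    average of March of each year at 5 m. Convexity preserves normalization.
    """
    if water.mode != "relative":
        raise ValueError("monthly_climatology expects a relative-mode matrix")
    recs = {s.sample_id: s for s in samples if s.compartment == "water"}
    cols = [c for c in water.sample_ids if c in recs]
    if not cols:
        raise ValueError("no water samples found in the matrix")

    # (depth, year, month, date) -> replicate-averaged vector
    by_date: dict[tuple[float, int, int], list[pd.Series]] = {}
    keyfun = lambda c: (recs[c].depth_m, recs[c].year, recs[c].month,
                        recs[c].date_start)
    for key, group in itertools.groupby(sorted(cols, key=keyfun), key=keyfun):
        g = list(group)
        vec = water.data[g].mean(axis=1)
        by_date.setdefault(key[:3], []).append(vec)

    # (depth, year, month) -> mean over dates; then mean over years
    by_year: dict[tuple[float, int], dict[int, pd.Series]] = {}
    for (depth, year, month), vecs in by_date.items():
        ym = by_year.setdefault((float(depth), int(month)), {})
        ym[year] = pd.concat(vecs, axis=1).mean(axis=1)

    data, n_years = {}, {}
    for key, years in by_year.items():
        data[key] = pd.concat(years.values(), axis=1).mean(axis=1)
        n_years[key] = len(years)
    return MonthlyClimatology(data=data, n_years=n_years)


def interpolate_missing_months(
    clim: MonthlyClimatology,
    months: Iterable[int] | None = None,
    allow_nearest: bool = False,
) -> MonthlyClimatology:
    """Fill missing (depth, month) climatology entries.

    A missing month is the elementwise mean of the two calendar-adjacent
    observed months at that depth (December and January are adjacent). If an
    adjacent month is also missing, a hard error names every unfillable
    (depth, month) — unless ``allow_nearest`` substitutes the calendar-nearest
    observed month instead. Target months default to all twelve.
    """
    target = sorted(set(months)) if months is not None else list(range(1, 13))
    data = dict(clim.data)
    n_years = dict(clim.n_years)
    interpolated = set(clim.interpolated)
    failures: list[tuple[float, int]] = []

    for depth in clim.depths:
        observed = {m for d, m in clim.data if d == depth}
        for month in target:
            if month in observed:
                continue
            prev = 12 if month == 1 else month - 1
            nxt = 1 if month == 12 else month + 1
            if prev in observed and nxt in observed:
                vec = (clim.data[(depth, prev)] + clim.data[(depth, nxt)]) / 2.0
            elif allow_nearest:
                def cyc_dist(m: int) -> int:
                    d = abs(m - month)
                    return min(d, 12 - d)
                nearest = min(sorted(observed), key=cyc_dist)
                vec = clim.data[(depth, nearest)].copy()
            else:
                failures.append((depth, month))
                continue
            data[(depth, month)] = vec
            n_years[(depth, month)] = 0
            interpolated.add((depth, month))

    if failures:
        raise ValueError(
            "cannot interpolate climatology (adjacent month also missing) for "
            f"(depth, month) pairs: {failures}")
    return MonthlyClimatology(data=data, n_years=n_years,
                              interpolated=interpolated)


def direct_reference(
    water: AbundanceMatrix, samples: Sequence[SampleRecord]
) -> MonthlyClimatology:
    """Climatology-free reference for contemporaneous deployments.

    Pools all water samples per depth (replicates and dates averaged) under
    the pseudo-month ``DIRECT_MONTH``, so trap samples are compared directly
    to the same-period water column.
    """
    if water.mode != "relative":
        raise ValueError("direct_reference expects a relative-mode matrix")
    recs = {s.sample_id: s for s in samples if s.compartment == "water"}
    cols = [c for c in water.sample_ids if c in recs]
    if not cols:
        raise ValueError("no water samples found in the matrix")
    data, n_years = {}, {}
    depths = sorted({recs[c].depth_m for c in cols})
    for depth in depths:
        g = [c for c in cols if recs[c].depth_m == depth]
        data[(float(depth), DIRECT_MONTH)] = water.data[g].mean(axis=1)
        n_years[(float(depth), DIRECT_MONTH)] = 1
    return MonthlyClimatology(data=data, n_years=n_years)


# ---------------------------------------------------------------------------
# SASV identification


def _n_tolerant_equal(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def identify_sasvs(
    trap_column: pd.Series,
    clim: MonthlyClimatology,
    depth_m: float,
    month: int,
    asvs: Sequence[AsvRecord] | Mapping[str, AsvRecord],
    *,
    trap_sample_id: str = "",
    min_presence: float = 0.0,
    n_wildcard: bool = False,
) -> SasvSet:
    """Shared ASVs between one trap sample and the water reference at a depth.

    Presence means relative abundance strictly above ``min_presence`` (default
    0). Identity is exact full-length sequence equality after uppercasing;
    with ``n_wildcard`` an N in either sequence matches any base at that
    position (for datasets without a uniformly masked position).
    """
    vec = clim.vector(depth_m, month)
    if isinstance(asvs, Mapping):
        seq_of = {k: v.dna_sequence for k, v in asvs.items()}
    else:
        seq_of = {a.asv_id: a.dna_sequence for a in asvs}

    water_present = [a for a in vec.index[vec > min_presence] if a in seq_of]
    trap_present = [a for a in trap_column.index[trap_column > min_presence]
                    if a in seq_of]
    water_by_seq: dict[str, set[str]] = {}
    for a in water_present:
        water_by_seq.setdefault(seq_of[a], set()).add(a)

    water_hit: set[str] = set()
    trap_hit: set[str] = set()
    for t in trap_present:
        seq = seq_of[t]
        matched = water_by_seq.get(seq, set())
        if not matched and n_wildcard:
            matched = {
                a for s, ids in water_by_seq.items()
                if _n_tolerant_equal(seq, s) for a in ids
            }
        if matched:
            trap_hit.add(t)
            water_hit |= matched
    return SasvSet(
        trap_sample_id=trap_sample_id or str(trap_column.name or ""),
        water_depth_m=float(depth_m),
        month=int(month),
        water_asv_ids=frozenset(water_hit),
        trap_asv_ids=frozenset(trap_hit),
    )


def water_fraction(sasv: SasvSet, clim: MonthlyClimatology) -> float:
    """Summed water-column (climatology) relative abundance of the shared set."""
    vec = clim.vector(sasv.water_depth_m, sasv.month)
    ids = [a for a in sasv.water_asv_ids if a in vec.index]
    return float(vec.loc[ids].sum()) if ids else 0.0


def trap_fraction(sasv: SasvSet, trap_column: pd.Series) -> float:
    """Summed trap relative abundance of the shared set."""
    ids = [a for a in sasv.trap_asv_ids if a in trap_column.index]
    return float(trap_column.loc[ids].sum()) if ids else 0.0


# ---------------------------------------------------------------------------
# aggregation


def fraction_table(
    trap: AbundanceMatrix,
    clim: MonthlyClimatology,
    asvs: Sequence[AsvRecord],
    trap_samples: Sequence[SampleRecord],
    *,
    direct: bool = False,
    min_presence: float = 0.0,
    n_wildcard: bool = False,
) -> tuple[pd.DataFrame, list[SasvSet]]:
    """Per-(trap interval, water depth) shared fractions, both directions.

    Returns a tidy table with columns ``interval_id, depth_m, month,
    water_fraction, trap_fraction, n_sasvs`` plus the underlying SASV sets.
    """
    if trap.mode != "relative":
        raise ValueError("fraction_table expects a relative-mode trap matrix")
    asv_map = {a.asv_id: a for a in asvs}
    rows = []
    sets: list[SasvSet] = []
    recs = {s.sample_id: s for s in trap_samples}
    for sid in trap.sample_ids:
        month = DIRECT_MONTH if direct else recs[sid].month
        col = trap.column(sid)
        for depth in clim.depths:
            ss = identify_sasvs(
                col, clim, depth, month, asv_map, trap_sample_id=sid,
                min_presence=min_presence, n_wildcard=n_wildcard)
            sets.append(ss)
            rows.append({
                "interval_id": sid,
                "depth_m": depth,
                "month": month,
                "water_fraction": water_fraction(ss, clim),
                "trap_fraction": trap_fraction(ss, col),
                "n_sasvs": len(ss.asv_ids),
            })
    return pd.DataFrame(rows), sets


def profile_over_time(
    fractions: pd.DataFrame, value: str = "water_fraction"
) -> DepthProfileStat:
    """Per-depth mean, sample sd (ddof=1; 0 for a single interval) and n
    across trap intervals (or replicates)."""
    if fractions.empty:
        raise ValueError("empty fraction table")
    rows = []
    for depth, g in fractions.groupby("depth_m", sort=True):
        vals = g[value].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"depth_m": float(depth), "mean": float(vals.mean()),
                     "sd": sd, "n": len(vals)})
    return DepthProfileStat(pd.DataFrame(rows))


def sasv_richness_by_depth(
    sasv_sets: Iterable[SasvSet], depth_m: float
) -> int:
    """Distinct ASVs in the union of the SASV sets for one origin depth."""
    ids: set[str] = set()
    for ss in sasv_sets:
        if ss.water_depth_m == float(depth_m):
            ids |= ss.asv_ids
    return len(ids)


def time_averaged_sasv_profiles(
    sasv_sets: Iterable[SasvSet], clim: MonthlyClimatology
) -> pd.DataFrame:
    """Time-averaged water-column profile of every SASV (ASV x depth).

    Each SASV's abundance at a depth is the mean of its climatology abundance
    over that depth's months; ASVs enter at every depth, zero where absent.
    Rows are SASV ids, columns the climatology depths.
    """
    sasv_ids: set[str] = set()
    for ss in sasv_sets:
        sasv_ids |= ss.water_asv_ids
    if not sasv_ids:
        raise ValueError("no SASVs in the supplied sets")
    depths = clim.depths
    prof = pd.DataFrame(0.0, index=sorted(sasv_ids), columns=depths)
    for depth in depths:
        months = clim.months_at(depth)
        acc = pd.concat([clim.vector(depth, m) for m in months], axis=1)
        mean = acc.mean(axis=1)
        common = [a for a in prof.index if a in mean.index]
        prof.loc[common, depth] = mean.loc[common]
    return prof
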