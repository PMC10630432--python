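"""Depth-zone ecotype classification of abundant SASVs.

Abundant SASVs (time-averaged water-column profile maximum >= 0.1% by
default) are assigned to one of six depth zones by the location of their
water-column depth maxima: Surface (5-75 m), DCM (100-150 m), Lower Euphotic
(175-200 m), Upper Mesopelagic (225-500 m), Lower Mesopelagic (770-1000 m) and
Bathypelagic (2000-4000 m).

Peak finding follows explicit conventions: an interior peak is a value
strictly greater than both neighbors; a plateau of equal values flanked by
smaller values counts once, at its shallowest depth; a boundary depth counts
as a peak when strictly greater than its single neighbor (``edge_peaks``,
default on — surface-maximal taxa must be classifiable). Bimodal profiles are
retained only when exactly one of the two maxima exceeds the depth-averaged
mean abundance (zone of that maximum) or both maxima fall in a single zone;
other bimodal profiles, and profiles with more than two maxima, are excluded
with a recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sasvtrace")

#: Default zone bounds (m), inclusive on both ends.
DEFAULT_ZONES: dict[str, tuple[float, float]] = {
    "Surface": (5, 75),
    "DCM": (100, 150),
    "LowerEuphotic": (175, 200),
    "UpperMesopelagic": (225, 500),
    "LowerMesopelagic": (770, 1000),
    "Bathypelagic": (2000, 4000),
}

#: Default abundance threshold: 0.1% of the water column at some depth.
ABUNDANCE_THRESHOLD = 0.001


@dataclass(frozen=True)
class DepthZoneMap:
    """Ordered, non-overlapping depth-zone bins.

    Depths falling between two bins (possible on a custom grid) are assigned
    to the zone whose bin midpoint is nearest.
    """

    zones: tuple[tuple[str, float, float], ...]

    @classmethod
    def default(cls) -> "DepthZoneMap":
        return cls(tuple((k, float(lo), float(hi))
                         for k, (lo, hi) in DEFAULT_ZONES.items()))

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "DepthZoneMap":
        zones = tuple(sorted(((k, float(v[0]), float(v[1])) for k, v in d.items()),
                             key=lambda t: t[1]))
        for (_, _, hi_a), (lb, lo_b, _) in zip(zones, zones[1:]):
            if lo_b <= hi_a:
                raise ValueError(f"zone bounds overlap at {lb!r}")
        return cls(zones)

    def zone_for_depth(self, depth_m: float, strict: bool = False) -> str:
        z = float(depth_m)
        for label, lo, hi in self.zones:
            if lo <= z <= hi:
                return label
        if strict:
            raise ValueError(
                f"depth {z} m falls outside every zone interval; supply a zone "
                "map covering the full grid or use strict=False")
        return min(self.zones, key=lambda t: abs((t[1] + t[2]) / 2 - z))[0]

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.zones]


@dataclass(frozen=True)
class ZoneAssignment:
    """Classification outcome for one abundant SASV."""

    asv_id: str
    peak_depths_m: tuple[float, ...]
    depth_averaged_mean: float
    retained: bool
    zone: str | None = None
    reason: str | None = None  # set when not retained

    def __post_init__(self) -> None:
        if self.retained and self.zone is None:
            raise ValueError(f"{self.asv_id}: retained but no zone assigned")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_depths_m)


def select_abundant(
    profiles: pd.DataFrame, threshold: float = ABUNDANCE_THRESHOLD
) -> pd.DataFrame:
    """Keep SASVs whose time-averaged profile maximum is >= threshold.

    The boundary is inclusive: a profile peaking exactly at the threshold is
    kept. ``profiles`` is ASV x depth (columns are depths in metres).
    """
    mask = profiles.max(axis=1) >= threshold
    return profiles.loc[mask]


def find_depth_maxima(
    depths: Sequence[float],
    values: Sequence[float],
    edge_peaks: bool = True,
) -> list[float]:
    """Depths of the local maxima of a shallow-to-deep profile.

    Interior peak: strictly greater than both neighbors. A plateau of equal
    values flanked on both sides by smaller values is one peak, reported at
    its shallowest depth. With ``edge_peaks`` (default), a boundary value
    strictly greater than its single neighbor is a peak; without it, boundary
    maxima are ignored (the behavior of common peak-finder defaults).
    """
    z = np.asarray(depths, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(z) < 3:
        raise ValueError("peak finding requires >= 3 depths")
    if len(z) != len(y):
        raise ValueError("depths and values must have equal length")
    if not np.all(np.diff(z) > 0):
        raise ValueError("depths must be strictly increasing")

    peaks: list[float] = []
    i, n = 0, len(y)
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1  # plateau [i, j]
        left_smaller = i > 0 and y[i - 1] < y[i]
        right_smaller = j < n - 1 and y[j + 1] < y[i]
        at_left_edge = i == 0
        at_right_edge = j == n - 1
        is_peak = False
        if not at_left_edge and not at_right_edge:
            is_peak = left_smaller and right_smaller
        elif edge_peaks and not (at_left_edge and at_right_edge):
            is_peak = (right_smaller if at_left_edge else left_smaller)
        if is_peak:
            peaks.append(float(z[i]))
        i = j + 1
    return peaks


def classify_and_assign(
    profiles: pd.DataFrame,
    zone_map: DepthZoneMap | None = None,
    edge_peaks: bool = True,
    strict_zones: bool = False,
) -> list[ZoneAssignment]:
    """Classify abundant SASV profiles into depth zones.

    ``profiles`` is ASV x depth (columns sorted shallow to deep). The
    depth-averaged mean is the unweighted mean over *all* grid depths.
    Single-peak SASVs are retained with the zone of their peak; bimodal SASVs
    under the two retention rules; >2 peaks are excluded as ``multimodal`` and
    peakless profiles as ``no_peak``.
    """
    zone_map = zone_map or DepthZoneMap.default()
    depths = [float(c) for c in profiles.columns]
    out: list[ZoneAssignment] = []
    for asv_id, row in profiles.iterrows():
        values = row.to_numpy(dtype=float)
        mean = float(values.mean())
        peaks = find_depth_maxima(depths, values, edge_peaks=edge_peaks)
        pk = tuple(peaks)
        if len(pk) == 0:
            out.append(ZoneAssignment(asv_id, pk, mean, False, reason="no_peak"))
            continue
        if len(pk) == 1:
            zone = zone_map.zone_for_depth(pk[0], strict=strict_zones)
            out.append(ZoneAssignment(asv_id, pk, mean, True, zone=zone))
            continue
        if len(pk) > 2:
            out.append(ZoneAssignment(asv_id, pk, mean, False,
                                      reason="multimodal"))
            continue
        # bimodal retention rules
        vals = {p: float(values[depths.index(p)]) for p in pk}
        above = [p for p in pk if vals[p] > mean]
        zones = [zone_map.zone_for_depth(p, strict=strict_zones) for p in pk]
        if len(above) == 1:  # rule 1: exactly one maximum exceeds the mean
            zone = zone_map.zone_for_depth(above[0], strict=strict_zones)
            out.append(ZoneAssignment(asv_id, pk, mean, True, zone=zone))
        elif zones[0] == zones[1]:  # rule 2: both maxima in one zone
            out.append(ZoneAssignment(asv_id, pk, mean, True, zone=zones[0]))
        else:
            out.append(ZoneAssignment(asv_id, pk, mean, False,
                                      reason="bimodal_ambiguous"))
    return out


def assignment_counts(assignments: Sequence[ZoneAssignment]) -> dict[str, int]:
    """Bookkeeping of the classification (the counts are exactly conserved:
    single + bimodal + multimodal + no_peak = total; retained + excluded =
    total)."""
    n_single = sum(1 for a in assignments if a.n_peaks == 1)
    n_bimodal = sum(1 for a in assignments if a.n_peaks == 2)
    n_multi = sum(1 for a in assignments if a.n_peaks > 2)
    n_nopeak = sum(1 for a in assignments if a.n_peaks == 0)
    n_ret = sum(1 for a in assignments if a.retained)
    return {
        "n_abundant": len(assignments),
        "n_single": n_single,
        "n_bimodal": n_bimodal,
        "n_multimodal": n_multi,
        "n_no_peak": n_nopeak,
        "n_retained": n_ret,
        "n_excluded": len(assignments) - n_ret,
        "n_bimodal_retained": sum(
            1 for a in assignments if a.retained and a.n_peaks == 2),
    }


def assignments_frame(assignments: Sequence[ZoneAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "asv_id": a.asv_id,
            "n_peaks": a.n_peaks,
            "peak_depths_m": ";".join(f"{p:g}" for p in a.peak_depths_m),
            "depth_averaged_mean": a.depth_averaged_mean,
            "retained": a.retained,
            "zone": a.zone or "",
            "reason": a.reason or "",
        })
    return pd.DataFrame(rows)


def zone_composition(
    assignments: Sequence[ZoneAssignment],
    taxonomy: Mapping[str, str],
    profiles: pd.DataFrame,
    zone_map: DepthZoneMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxon composition of each depth zone and per-zone coverage.

    For every zone, retained SASVs assigned to it are grouped by taxon label
    (``"Unknown"`` when missing) and their mean abundance over the zone's grid
    depths is summed. Coverage is the abundance at a zone's depths of the
    *whole retained set* (whatever zone each member is assigned to) as a
    fraction of the summed abundance of all profiled SASVs there — how much of
    the SASV signal at those depths the retained subset captures. Returns
    ``(composition, coverage)`` tables.
    """
    zone_map = zone_map or DepthZoneMap.default()
    depths = [float(c) for c in profiles.columns]
    depth_zone = {d: zone_map.zone_for_depth(d) for d in depths}
    retained_all = [a for a in assignments if a.retained]
    comp_rows, cov_rows = [], []
    for label in zone_map.labels:
        zdepths = [d for d in depths if depth_zone[d] == label]
        if not zdepths:
            continue
        retained_here = [a for a in retained_all if a.zone == label]
        by_taxon: dict[str, float] = {}
        for a in retained_here:
            taxon = taxonomy.get(a.asv_id, "Unknown") or "Unknown"
            abund = float(profiles.loc[a.asv_id, zdepths].mean())
            by_taxon[taxon] = by_taxon.get(taxon, 0.0) + abund
        for taxon in sorted(by_taxon):
            comp_rows.append({"zone": label, "taxon": taxon,
                              "abundance": by_taxon[taxon]})
        total = float(profiles[zdepths].to_numpy().mean(axis=1).sum())
        got = sum(float(profiles.loc[a.asv_id, zdepths].mean())
                  for a in retained_all)
        cov_rows.append({
            "zone": label,
            "coverage": got / total if total > 0 else float("nan"),
            "n_retained": len(retained_here),
        })
    return pd.DataFrame(comp_rows), pd.DataFrame(cov_rows)
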