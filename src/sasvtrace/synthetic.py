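"""Synthetic water-column / sediment-trap amplicon datasets with known truth.

The generator plants every quantity the analysis pipeline estimates, so each
stage can be verified by parameter recovery:

* a piecewise power-law **shared fraction** curve for the water column —
  S(Z) = S_ref (Z/Z_ref)^b_upper between the reference depth and a transition
  depth Z_trans, an increasing power law S(Z_trans) (Z/Z_trans)^b_deep below
  it, and a constant S_ref shallower than Z_ref (upper-ocean profiles are
  approximately flat above the export reference depth);
* a trap-side power law T(Z) = T_ref (Z/Z_ref_trap)^b_trap for the summed trap
  relative abundance attributable to each water-column origin depth;
* depth-zone **ecotypes**: taxa whose water-column profiles are Gaussian bumps
  on log10-depth (truncated at 3 sigma), unimodal or bimodal, peaking inside a
  named depth zone;
* **copiotroph pulses**: designated deep-water taxa whose trap abundance is
  multiplied during flagged summer-export-pulse (SEP) intervals, together with
  particulate C/N flux records that exceed 1.5x the annual reference means in
  SEP intervals only.

At each depth the community is: the ecotype bumps (shared with the trap), one
depth-specific *shared filler* ASV topping the shared mass up to exactly S(Z),
and one depth-specific *unshared filler* carrying the remaining 1 - S(Z).
In "noiseless" mode the matrices hold these exact expected fractions; with
``reads_per_sample`` set, counts are drawn multinomially from them.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    AbundanceMatrix,
    AsvRecord,
    FluxRecord,
    SampleRecord,
    write_counts_table,
    write_fasta,
    write_flux,
    write_metadata,
    write_results,
)

#: Sampled depth horizons (m), spanning the near-surface to the abyssal trap.
DEFAULT_DEPTH_GRID: tuple[float, ...] = (
    5, 25, 45, 75, 100, 125, 150, 175, 200, 225,
    250, 300, 400, 500, 770, 1000, 2000, 3000, 4000,
)

_SEQ_LEN = 250
_TRUNC_SIGMA = 3.0  # ecotype bumps are zero beyond this many sigma (log10 depth)


@dataclass(frozen=True)
class SharedFractionCurve:
    """Planted water-column shared-fraction curve S(Z).

    Defaults anchor 82.9% at 75 m with attenuation exponent -1.34 down to a
    250 m transition, then increase with exponent +0.31 — the regime observed
    for abyssal-trap-shared taxa in the subtropical North Pacific.
    """

    s_ref: float = 0.829
    z_ref: float = 75.0
    b_upper: float = -1.34
    z_trans: float = 250.0
    b_deep: float = 0.31

    def __call__(self, depth_m: float) -> float:
        z = float(depth_m)
        if z <= 0:
            raise ValueError("depth must be positive")
        if z <= self.z_ref:
            return self.s_ref
        if z <= self.z_trans:
            return self.s_ref * (z / self.z_ref) ** self.b_upper
        s_trans = self.s_ref * (self.z_trans / self.z_ref) ** self.b_upper
        return s_trans * (z / self.z_trans) ** self.b_deep


@dataclass(frozen=True)
class TrapFractionCurve:
    """Planted trap-side curve T(Z): trap mass attributed to origin depth Z."""

    t_ref: float = 0.04
    z_ref: float = 250.0
    b: float = 0.31

    def __call__(self, depth_m: float) -> float:
        return self.t_ref * (float(depth_m) / self.z_ref) ** self.b


@dataclass(frozen=True)
class Ecotype:
    """One planted depth-zone taxon.

    ``peak_depths_m`` has one entry (unimodal) or two (bimodal); amplitudes are
    absolute water-column relative abundances at the peak(s). ``width`` is the
    Gaussian sigma in log10-depth units.
    """

    taxon: str
    zone: str
    peak_depths_m: tuple[float, ...]
    amplitudes: tuple[float, ...]
    width: float = 0.12
    trap_abundance: float = 2e-4

    def __post_init__(self) -> None:
        if len(self.peak_depths_m) not in (1, 2):
            raise ValueError(f"ecotype {self.taxon!r}: 1 or 2 peaks supported")
        if len(self.amplitudes) != len(self.peak_depths_m):
            raise ValueError(f"ecotype {self.taxon!r}: one amplitude per peak")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError(f"ecotype {self.taxon!r}: amplitudes must be > 0")

    def profile(self, depth_grid: np.ndarray) -> np.ndarray:
        logz = np.log10(np.asarray(depth_grid, dtype=float))
        out = np.zeros_like(logz)
        for peak, amp in zip(self.peak_depths_m, self.amplitudes):
            d = (logz - math.log10(peak)) / self.width
            bump = amp * np.exp(-0.5 * d * d)
            bump[np.abs(d) > _TRUNC_SIGMA] = 0.0
            out += bump
        return out


def default_ecotypes() -> list[Ecotype]:
    """A realistic default community: 19 taxa across the six depth zones,
    patterned on the dominant open-ocean clades of each stratum."""
    E = Ecotype
    return [
        # Surface 5-75 m: photoautotrophs and surface oligotrophs
        E("Prochlorococcus", "Surface", (25,), (0.10,)),
        E("Synechococcus", "Surface", (5,), (0.04,)),
        E("SAR11_CladeIa", "Surface", (45,), (0.08,)),
        E("AEGEAN169", "Surface", (25,), (0.03,)),
        # DCM 100-150 m
        E("Ca_Actinomarina", "DCM", (100,), (0.03,)),
        E("SAR86", "DCM", (125,), (0.03,)),
        E("Prochlorococcus_LL", "DCM", (125,), (0.04,)),
        # Lower euphotic 175-200 m: nitrifiers appear
        E("Ca_Nitrosopelagicus", "LowerEuphotic", (175,), (0.02,)),
        E("SAR11_CladeII", "LowerEuphotic", (200,), (0.02,)),
        # Upper mesopelagic 225-500 m
        E("SAR324", "UpperMesopelagic", (300,), (0.025,)),
        E("SAR406", "UpperMesopelagic", (400,), (0.02,)),
        E("HOC36", "UpperMesopelagic", (250,), (0.015,)),
        # Lower mesopelagic 770-1000 m
        E("Nitrosopumilaceae", "LowerMesopelagic", (770,), (0.02,)),
        E("SAR202", "LowerMesopelagic", (1000,), (0.02,)),
        E("UBA10353", "LowerMesopelagic", (770,), (0.012,)),
        # Bathypelagic 2000-4000 m
        E("SAR202_deep", "Bathypelagic", (3000,), (0.02,)),
        E("Marinimicrobia_deep", "Bathypelagic", (2000,), (0.015,)),
        E("MGI_deep", "Bathypelagic", (4000,), (0.02,)),
        E("Sva0996", "Bathypelagic", (2000,), (0.01,)),
    ]


def _default_months() -> tuple[tuple[int, int], ...]:
    return tuple((y, m) for y in (2015, 2016) for m in range(1, 13))


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic study.

    Defaults emulate the three-year abyssal-trap study design: a 19-depth grid
    from 5 to 4000 m, two years of monthly water-column sampling (so every
    calendar month has two years to average), 58 twelve-day trap collection
    intervals, and SEP pulses in July/August.
    """

    depth_grid: tuple[float, ...] = DEFAULT_DEPTH_GRID
    months: tuple[tuple[int, int], ...] = field(default_factory=_default_months)
    n_trap_intervals: int = 58
    trap_start: dt.date = dt.date(2014, 3, 1)
    trap_interval_days: int = 12
    trap_depth_m: float = 4000.0
    ecotypes: tuple[Ecotype, ...] = field(
        default_factory=lambda: tuple(default_ecotypes()))
    shared_curve: SharedFractionCurve = field(default_factory=SharedFractionCurve)
    trap_curve: TrapFractionCurve = field(default_factory=TrapFractionCurve)
    n_copiotrophs: int = 8
    copiotroph_water_abundance: float = 1e-4
    copiotroph_trap_abundance: float = 0.005
    sep_months: tuple[int, ...] = (7, 8)
    sep_intervals: tuple[str, ...] | None = None  # explicit override
    sep_multiplier: float = 5.0
    pc_ref_mean: float = 25.0  # mg C m^-2 d^-1, abyssal-trap scale
    pn_ref_mean: float = 3.0
    reads_per_sample: int | None = None  # None = noiseless expected fractions
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.depth_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 3:
            raise ValueError("depth_grid needs at least 3 depths")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("depth_grid must be strictly increasing")
        c = self.shared_curve
        if not (0 < c.s_ref <= 1):
            raise ValueError("s_ref must be in (0, 1]")
        if not (grid[0] <= c.z_ref <= grid[-1] and grid[0] <= c.z_trans <= grid[-1]):
            raise ValueError("z_ref and z_trans must lie within the depth grid span")
        if self.sep_multiplier < 1:
            raise ValueError("sep_multiplier must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    shared_fraction: dict[float, float]          # depth -> planted S(Z)
    trap_fraction: dict[float, float]            # depth -> planted T(Z)
    ecotype_zone: dict[str, str]                 # asv_id -> planted zone
    ecotype_peaks: dict[str, tuple[float, ...]]  # asv_id -> planted peak depth(s)
    sep_enriched_asvs: tuple[str, ...]
    sep_interval_ids: tuple[str, ...]
    b_upper: float
    b_deep: float
    b_trap: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimResult:
    water: AbundanceMatrix
    water_samples: list[SampleRecord]
    trap: AbundanceMatrix
    trap_samples: list[SampleRecord]
    asvs: list[AsvRecord]
    flux: list[FluxRecord]
    truth: SimTruth
    config: SimConfig


def expected_shared_fraction(cfg: SimConfig, depth_m: float) -> float:
    """Planted water-column shared fraction S(Z) at a depth within the grid."""
    grid = cfg.depth_grid
    if not (grid[0] <= depth_m <= grid[-1]):
        raise ValueError(
            f"depth {depth_m} m outside grid span [{grid[0]}, {grid[-1]}] m")
    return cfg.shared_curve(depth_m)


def _random_sequence(rng: np.random.Generator, existing: set[str]) -> str:
    letters = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(letters, size=_SEQ_LEN))
        if seq not in existing:
            existing.add(seq)
            return seq


def _trap_intervals(cfg: SimConfig) -> list[tuple[str, dt.date, dt.date]]:
    out = []
    start = cfg.trap_start
    for _ in range(cfg.n_trap_intervals):
        end = start + dt.timedelta(days=cfg.trap_interval_days)
        sid = f"T_{start.isoformat()}"
        out.append((sid, start, end))
        start = end
    return out


def simulate_dataset(cfg: SimConfig | None = None) -> SimResult:
    """Generate a complete synthetic study with ground truth.

    Raises ``ValueError`` before any sampling if the planted curves are
    infeasible (S(Z) > 1, ecotype mass exceeding S(Z), or trap mass
    over-committed).
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.depth_grid, dtype=float)
    nz = len(grid)

    s_target = np.array([cfg.shared_curve(z) for z in grid])
    if np.any(s_target > 1 + 1e-12):
        bad = grid[s_target > 1 + 1e-12]
        raise ValueError(f"planted shared fraction exceeds 1 at depths {bad.tolist()}")
    t_target = np.array([cfg.trap_curve(z) for z in grid])

    # --- ASV inventory --------------------------------------------------
    eco_ids = [f"eco_{e.taxon}" for e in cfg.ecotypes]
    eco_profiles = np.vstack([e.profile(grid) for e in cfg.ecotypes]) \
        if cfg.ecotypes else np.zeros((0, nz))
    copio_ids = [f"copio_{i:02d}" for i in range(cfg.n_copiotrophs)]
    sfill_ids = [f"sharedfill_{int(z):04d}" for z in grid]
    ufill_ids = [f"unsharedfill_{int(z):04d}" for z in grid]
    trapfill_id = "trapfill_0000"
    asv_ids = eco_ids + copio_ids + sfill_ids + ufill_ids + [trapfill_id]

    # --- water composition per depth -------------------------------------
    copio_water = np.zeros((cfg.n_copiotrophs, nz))
    if cfg.n_copiotrophs:
        copio_water[:, -1] = cfg.copiotroph_water_abundance  # deepest depth only
    eco_mass = eco_profiles.sum(axis=0) + copio_water.sum(axis=0)
    sfill = s_target - eco_mass
    if np.any(sfill <= 0):
        bad = grid[sfill <= 0].tolist()
        raise ValueError(
            f"ecotype mass exceeds the planted shared fraction at depths {bad}; "
            "reduce amplitudes or raise the shared curve")
    ufill = 1.0 - s_target

    water_comp = np.zeros((len(asv_ids), nz))
    water_comp[: len(eco_ids)] = eco_profiles
    water_comp[len(eco_ids): len(eco_ids) + cfg.n_copiotrophs] = copio_water
    for j in range(nz):
        water_comp[len(eco_ids) + cfg.n_copiotrophs + j, j] = sfill[j]
        water_comp[len(eco_ids) + cfg.n_copiotrophs + nz + j, j] = ufill[j]
    assert np.allclose(water_comp.sum(axis=0), 1.0, atol=1e-12)

    # --- trap composition (base, non-SEP) --------------------------------
    eco_present = water_comp[: len(eco_ids)] > 0  # ecotype x depth support
    trap_base = np.zeros(len(asv_ids))
    trap_base[: len(eco_ids)] = [e.trap_abundance for e in cfg.ecotypes]
    trap_base[len(eco_ids): len(eco_ids) + cfg.n_copiotrophs] = (
        cfg.copiotroph_trap_abundance)
    for j in range(nz):
        committed = trap_base[: len(eco_ids)][eco_present[:, j]].sum()
        if j == nz - 1:
            committed += cfg.n_copiotrophs * cfg.copiotroph_trap_abundance
        t_fill = t_target[j] - committed
        if t_fill <= 0:
            raise ValueError(
                f"planted trap fraction {t_target[j]:.4f} at {grid[j]} m cannot "
                "accommodate the ecotype/copiotroph trap mass")
        trap_base[len(eco_ids) + cfg.n_copiotrophs + j] = t_fill
    shared_mass = trap_base.sum()
    if shared_mass >= 1:
        raise ValueError(
            f"total planted trap shared mass {shared_mass:.3f} >= 1; lower the "
            "trap curve")
    trap_base[-1] = 1.0 - shared_mass  # trap-only filler
    assert abs(trap_base.sum() - 1.0) < 1e-12

    # --- samples ----------------------------------------------------------
    water_samples: list[SampleRecord] = []
    water_cols: dict[str, np.ndarray] = {}
    for (year, month) in cfg.months:
        date = dt.date(year, month, 15)
        for j, z in enumerate(grid):
            sid = f"W_{year}-{month:02d}_{int(z):04d}"
            water_samples.append(SampleRecord(
                sample_id=sid, compartment="water", depth_m=float(z),
                date_start=date))
            water_cols[sid] = water_comp[:, j]

    intervals = _trap_intervals(cfg)
    if cfg.sep_intervals is not None:
        sep_ids = set(cfg.sep_intervals)
    else:
        sep_ids = {
            sid for sid, s, e in intervals
            if (s + (e - s) / 2).month in cfg.sep_months
        }
    copio_slice = slice(len(eco_ids), len(eco_ids) + cfg.n_copiotrophs)
    trap_samples: list[SampleRecord] = []
    trap_cols: dict[str, np.ndarray] = {}
    for sid, s, e in intervals:
        trap_samples.append(SampleRecord(
            sample_id=sid, compartment="trap", depth_m=cfg.trap_depth_m,
            date_start=s, date_end=e))
        col = trap_base.copy()
        if sid in sep_ids and cfg.n_copiotrophs:
            col[copio_slice] *= cfg.sep_multiplier
            col = col / col.sum()
        trap_cols[sid] = col

    # --- sequences and matrices ------------------------------------------
    existing: set[str] = set()
    asvs = [AsvRecord(a, _random_sequence(rng, existing)) for a in asv_ids]

    def build_matrix(cols: dict[str, np.ndarray]) -> AbundanceMatrix:
        df = pd.DataFrame(cols, index=asv_ids)
        if cfg.reads_per_sample is None:
            return AbundanceMatrix(df, mode="relative")
        counts = {
            sid: rng.multinomial(cfg.reads_per_sample, p)
            for sid, p in cols.items()
        }
        return AbundanceMatrix(
            pd.DataFrame(counts, index=asv_ids, dtype=float), mode="counts")

    water_m = build_matrix(water_cols)
    trap_m = build_matrix(trap_cols)

    # --- flux records ------------------------------------------------------
    flux: list[FluxRecord] = []
    for sid, s, e in intervals:
        if sid in sep_ids:
            pc = cfg.pc_ref_mean * rng.uniform(1.6, 2.2)
            pn = cfg.pn_ref_mean * rng.uniform(1.6, 2.2)
        else:
            pc = cfg.pc_ref_mean * rng.uniform(0.5, 1.3)
            pn = cfg.pn_ref_mean * rng.uniform(0.5, 1.3)
        flux.append(FluxRecord(s, e, pc, pn, cfg.pc_ref_mean, cfg.pn_ref_mean))

    truth = SimTruth(
        shared_fraction={float(z): float(s) for z, s in zip(grid, s_target)},
        trap_fraction={float(z): float(t) for z, t in zip(grid, t_target)},
        ecotype_zone={f"eco_{e.taxon}": e.zone for e in cfg.ecotypes},
        ecotype_peaks={f"eco_{e.taxon}": e.peak_depths_m for e in cfg.ecotypes},
        sep_enriched_asvs=tuple(copio_ids),
        sep_interval_ids=tuple(sorted(sep_ids)),
        b_upper=cfg.shared_curve.b_upper,
        b_deep=cfg.shared_curve.b_deep,
        b_trap=cfg.trap_curve.b,
    )
    return SimResult(water_m, water_samples, trap_m, trap_samples, asvs,
                     flux, truth, cfg)


def _bump(grid_log: np.ndarray, peak: float, amp: float, sigma: float) -> np.ndarray:
    d = (grid_log - math.log10(peak)) / sigma
    out = amp * np.exp(-0.5 * d * d)
    out[np.abs(d) > _TRUNC_SIGMA] = 0.0
    return out


def planted_zone_profiles(
    n_unimodal: int = 100,
    n_bimodal_rule1: int = 10,
    n_bimodal_rule2: int = 5,
    n_bimodal_ambiguous: int = 5,
    depth_grid: tuple[float, ...] = DEFAULT_DEPTH_GRID,
    zones: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Planted SASV depth profiles with known peak structure and zones.

    Returns ``(profiles, truth)``: an ASV x depth table of time-averaged
    water-column abundances and a mapping from ASV id to the intended zone
    label (``None`` for profiles built to fail both bimodal retention rules).
    Construction invariants — each intended peak is a strict local maximum,
    bumps of one profile never overlap, and the above/below-mean pattern
    matches the intended retention rule — are verified numerically and
    asserted, so the truth labels are guaranteed by construction.

    Unimodal profiles peak at a random in-zone grid depth. Rule-1 bimodal
    profiles have one dominant peak (above the profile's depth-averaged mean)
    and one minor peak below it, in different zones; rule-2 profiles have two
    above-mean peaks inside a single zone; "ambiguous" profiles have two
    above-mean peaks in different zones.
    """
    if zones is None:
        zones = {
            "Surface": (5, 75), "DCM": (100, 150), "LowerEuphotic": (175, 200),
            "UpperMesopelagic": (225, 500), "LowerMesopelagic": (770, 1000),
            "Bathypelagic": (2000, 4000),
        }
    rng = np.random.default_rng(seed)
    grid = np.asarray(depth_grid, dtype=float)
    grid_log = np.log10(grid)
    zone_of = {}
    for z in grid:
        for label, (lo, hi) in zones.items():
            if lo <= z <= hi:
                zone_of[float(z)] = label
    zone_depths = {label: [z for z in grid if zone_of.get(float(z)) == label]
                   for label in zones}

    def strict_peaks(vals: np.ndarray) -> list[int]:
        # independent check: strict local maxima incl. edges, no plateaus
        idx = []
        for i in range(len(vals)):
            left_ok = i == 0 or vals[i - 1] < vals[i]
            right_ok = i == len(vals) - 1 or vals[i + 1] < vals[i]
            if vals[i] > 0 and left_ok and right_ok:
                idx.append(i)
        return idx

    profiles: dict[str, np.ndarray] = {}
    truth: dict[str, str | None] = {}

    labels = list(zones)
    for k in range(n_unimodal):
        label = labels[k % len(labels)]
        peak = float(rng.choice(zone_depths[label]))
        amp = float(rng.uniform(0.005, 0.05))
        prof = _bump(grid_log, peak, amp, 0.08)
        assert len(strict_peaks(prof)) == 1
        aid = f"uni_{k:03d}"
        profiles[aid], truth[aid] = prof, label

    def far_pair() -> tuple[float, float]:
        while True:
            a, b = rng.choice(grid, size=2, replace=False)
            if (zone_of.get(float(a)) and zone_of.get(float(b))
                    and zone_of[float(a)] != zone_of[float(b)]
                    and abs(math.log10(a) - math.log10(b)) >= 0.55):
                return float(a), float(b)

    for k in range(n_bimodal_rule1):
        hi_peak, lo_peak = far_pair()
        prof = (_bump(grid_log, hi_peak, 0.06, 0.08)
                + _bump(grid_log, lo_peak, 0.002, 0.08))
        mean = prof.mean()
        assert 0.002 < mean < 0.06, "rule-1 mean condition failed"
        assert len(strict_peaks(prof)) == 2
        aid = f"bi1_{k:03d}"
        profiles[aid], truth[aid] = prof, zone_of[hi_peak]

    rule2_pairs = [("Surface", 5, 45), ("UpperMesopelagic", 225, 500),
                   ("Bathypelagic", 2000, 4000)]
    for k in range(n_bimodal_rule2):
        label, p1, p2 = rule2_pairs[k % len(rule2_pairs)]
        amp = float(rng.uniform(0.04, 0.06))
        prof = (_bump(grid_log, p1, amp, 0.04)
                + _bump(grid_log, p2, amp * 0.9, 0.04))
        mean = prof.mean()
        assert prof[grid == p1][0] > mean and prof[grid == p2][0] > mean
        assert len(strict_peaks(prof)) == 2
        aid = f"bi2_{k:03d}"
        profiles[aid], truth[aid] = prof, label

    for k in range(n_bimodal_ambiguous):
        p1, p2 = far_pair()
        prof = (_bump(grid_log, p1, 0.05, 0.08)
                + _bump(grid_log, p2, 0.045, 0.08))
        mean = prof.mean()
        assert prof[grid == p1][0] > mean and prof[grid == p2][0] > mean
        assert len(strict_peaks(prof)) == 2
        aid = f"biX_{k:03d}"
        profiles[aid], truth[aid] = prof, None

    table = pd.DataFrame(profiles, index=[float(z) for z in grid]).T
    return table, truth


def write_dataset(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the same formats :mod:`io_tables` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "water_counts": write_counts_table(sim.water, outdir / "water_counts.tsv"),
        "trap_counts": write_counts_table(sim.trap, outdir / "trap_counts.tsv"),
        "fasta": write_fasta(sim.asvs, outdir / "asvs.fasta"),
        "metadata": write_metadata(
            sim.water_samples + sim.trap_samples, outdir / "metadata.csv"),
        "flux": write_flux(sim.flux, outdir / "flux.csv"),
        "truth": write_results(sim.truth, outdir / "truth.json"),
    }
    return paths
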