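"""Summer export pulse (SEP) flagging and trap enrichment testing.

The SEP is the seasonal window in which deep-trap particulate carbon *and*
nitrogen fluxes reach at least 150% of their long-term annual means. Trap
collection intervals are flagged from flux records; SASVs whose trap relative
abundances are significantly higher during SEP intervals (Welch's t test,
two-sided, plus a direction gate) are reported as SEP-enriched. No
multiple-testing correction is applied by default; Benjamini-Hochberg FDR is
available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceMatrix, FluxRecord, SampleRecord

logger = logging.getLogger("sasvtrace")

SEP_FACTOR = 1.5


@dataclass
class SepCalendar:
    """Per-trap-interval SEP flags with the flux ratios behind them.

    ``table`` columns: interval_id, is_sep, pc_ratio, pn_ratio. Intervals with
    no flux record are listed in ``unknown`` and excluded downstream.
    """

    table: pd.DataFrame
    unknown: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def sep_ids(self) -> list[str]:
        t = self.table
        return t.loc[t["is_sep"], "interval_id"].tolist()

    @property
    def nonsep_ids(self) -> list[str]:
        t = self.table
        return t.loc[~t["is_sep"], "interval_id"].tolist()


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ok: bool = True
    note: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    asv_id: str
    mean_sep: float
    mean_nonsep: float
    t_stat: float
    df: float
    p_value: float
    enriched: bool
    q_value: float | None = None
    note: str = ""


def flag_sep(
    flux: Sequence[FluxRecord],
    trap_samples: Sequence[SampleRecord] | None = None,
    factor: float = SEP_FACTOR,
    require_both: bool = True,
) -> SepCalendar:
    """Flag SEP intervals from flux records.

    An interval is SEP when its particulate-carbon and particulate-nitrogen
    flux ratios (flux / annual reference mean) are both >= ``factor``
    (inclusive: exactly 150% counts). ``require_both=False`` relaxes the rule
    to either ratio. When ``trap_samples`` is given, flux records are matched
    to trap intervals by start date and unmatched intervals are flagged
    unknown with a warning.
    """
    rows = []
    flux_by_start = {f.interval_start: f for f in flux}
    unknown: list[str] = []
    if trap_samples is not None:
        for s in trap_samples:
            if s.compartment != "trap":
                continue
            f = flux_by_start.get(s.date_start)
            if f is None:
                unknown.append(s.sample_id)
                continue
            rows.append((s.sample_id, f))
        if unknown:
            logger.warning(
                "no flux record for %d trap interval(s); excluded from SEP "
                "analysis: %s", len(unknown), unknown[:5])
    else:
        for f in flux:
            rows.append((f"T_{f.interval_start.isoformat()}", f))

    out = []
    for iid, f in rows:
        pc_ratio = f.pc_flux / f.pc_ref_mean
        pn_ratio = f.pn_flux / f.pn_ref_mean
        if require_both:
            is_sep = pc_ratio >= factor and pn_ratio >= factor
        else:
            is_sep = pc_ratio >= factor or pn_ratio >= factor
        out.append({"interval_id": iid, "is_sep": bool(is_sep),
                    "pc_ratio": pc_ratio, "pn_ratio": pn_ratio})
    return SepCalendar(pd.DataFrame(out), unknown=tuple(unknown))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t test, two-sided.

    t = (x̄ − ȳ) / sqrt(sx²/nx + sy²/ny) with Welch–Satterthwaite degrees of
    freedom. Groups smaller than two, or zero variance in both groups, yield a
    flagged undefined result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return WelchResult(float("nan"), float("nan"), float("nan"), ok=False,
                           note="group size < 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return WelchResult(float("nan"), float("nan"), float("nan"), ok=False,
                           note="zero variance in both groups")
    se2x, se2y = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (
        se2x ** 2 / (len(x) - 1) + se2y ** 2 / (len(y) - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def enriched_sasvs(
    trap: AbundanceMatrix | pd.DataFrame,
    calendar: SepCalendar,
    alpha: float = 0.05,
    fdr: bool = False,
    asv_ids: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """SASVs significantly more abundant in the trap during SEP intervals.

    ``trap`` holds relative abundances with trap intervals as columns. Every
    ASV present in any trap sample is tested (restrict with ``asv_ids``);
    enrichment requires two-sided p < alpha *and* mean_sep > mean_nonsep.
    With ``fdr``, Benjamini–Hochberg q-values replace raw p in the decision.
    At least two intervals are required in each stratum.
    """
    data = trap.data if isinstance(trap, AbundanceMatrix) else trap
    if isinstance(trap, AbundanceMatrix) and trap.mode != "relative":
        raise ValueError("enriched_sasvs expects relative abundances")
    sep_cols = [c for c in calendar.sep_ids if c in data.columns]
    non_cols = [c for c in calendar.nonsep_ids if c in data.columns]
    if len(sep_cols) < 2 or len(non_cols) < 2:
        raise ValueError(
            f"need >= 2 intervals per stratum; got {len(sep_cols)} SEP and "
            f"{len(non_cols)} non-SEP")
    rows = data.index if asv_ids is None else [a for a in asv_ids
                                               if a in data.index]
    results: list[EnrichmentResult] = []
    for asv in rows:
        xs = data.loc[asv, sep_cols].to_numpy(dtype=float)
        ys = data.loc[asv, non_cols].to_numpy(dtype=float)
        if xs.sum() == 0 and ys.sum() == 0:
            continue  # absent from every trap sample
        w = welch_t_test(xs, ys)
        results.append(EnrichmentResult(
            asv_id=str(asv),
            mean_sep=float(xs.mean()),
            mean_nonsep=float(ys.mean()),
            t_stat=w.t, df=w.df, p_value=w.p,
            enriched=bool(w.ok and w.p < alpha and xs.mean() > ys.mean()),
            note=w.note,
        ))
    if fdr:
        valid = [i for i, r in enumerate(results) if not math.isnan(r.p_value)]
        if valid:
            q = stats.false_discovery_control(
                [results[i].p_value for i in valid], method="bh")
            for i, qv in zip(valid, q):
                r = results[i]
                results[i] = EnrichmentResult(
                    asv_id=r.asv_id, mean_sep=r.mean_sep,
                    mean_nonsep=r.mean_nonsep, t_stat=r.t_stat, df=r.df,
                    p_value=r.p_value, q_value=float(qv),
                    enriched=bool(qv < alpha and r.mean_sep > r.mean_nonsep),
                    note=r.note)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "asv_id": r.asv_id, "mean_sep": r.mean_sep,
            "mean_nonsep": r.mean_nonsep, "t_stat": r.t_stat, "df": r.df,
            "p_value": r.p_value,
            "q_value": np.nan if r.q_value is None else r.q_value,
            "enriched": r.enriched, "note": r.note,
        })
    return pd.DataFrame(rows)
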