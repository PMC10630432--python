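"""Input/output and the canonical in-memory data model.

All downstream stages consume the containers defined here: :class:`AsvRecord`
(an exact 16S amplicon sequence variant), :class:`SampleRecord` (one water or
sediment-trap sample with depth and collection dates), :class:`AbundanceMatrix`
(ASV x sample counts or per-sample relative abundances) and :class:`FluxRecord`
(particulate C/N flux for one trap collection interval).

External formats are deliberately plain text: TSV/CSV count tables (rows keyed
by ASV id, columns by sample id; delimiter autodetected), FASTA for ASV
sequences, and CSV for sample metadata and flux series.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("sasvtrace")

_NUCLEOTIDES = frozenset("ACGTN")

#: Tolerance for "each relative-abundance column sums to one".
COLUMN_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AsvRecord:
    """One amplicon sequence variant.

    ``dna_sequence`` is uppercase A/C/G/T/N (U is mapped to T on load; an N may
    mark a masked low-quality position). ``taxonomy`` is an optional ordered
    tuple of rank labels, domain first.
    """

    asv_id: str
    dna_sequence: str
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        seq = self.dna_sequence.upper().replace("U", "T")
        object.__setattr__(self, "dna_sequence", seq)
        if not seq:
            raise ValueError(f"ASV {self.asv_id!r}: empty sequence")
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise ValueError(
                f"ASV {self.asv_id!r}: non-IUPAC characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: a water-column bottle or a trap interval.

    Water samples carry a single collection date; sediment-trap samples carry a
    collection interval. ``month`` is derived: the collection month for water
    samples, the month of the interval midpoint for traps (a trap interval
    spanning a month boundary is attributed to the month its midpoint falls in).
    """

    sample_id: str
    compartment: str  # "water" | "trap"
    depth_m: float
    date_start: dt.date
    date_end: dt.date | None = None
    replicate: str | None = None
    n_reads: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in ("water", "trap"):
            raise ValueError(
                f"sample {self.sample_id!r}: compartment must be 'water' or "
                f"'trap', got {self.compartment!r}"
            )
        if not self.depth_m > 0:
            raise ValueError(f"sample {self.sample_id!r}: depth_m must be > 0")
        if self.date_end is not None and self.date_start > self.date_end:
            raise ValueError(
                f"sample {self.sample_id!r}: interval_start > interval_end"
            )
        if self.n_reads is not None and self.n_reads < 0:
            raise ValueError(f"sample {self.sample_id!r}: n_reads < 0")

    @property
    def midpoint_date(self) -> dt.date:
        if self.date_end is None:
            return self.date_start
        return self.date_start + (self.date_end - self.date_start) / 2

    @property
    def month(self) -> int:
        return self.midpoint_date.month

    @property
    def year(self) -> int:
        return self.midpoint_date.year


@dataclass
class AbundanceMatrix:
    """ASV x sample abundances, either raw counts or per-sample fractions.

    Wraps a :class:`pandas.DataFrame` with ASV ids on the index and sample ids
    on the columns. ``mode`` is ``"counts"`` or ``"relative"``; in relative
    mode every column sums to one within ``COLUMN_SUM_TOL`` unless the sample
    was all-zero, in which case it is preserved as zero and listed in
    ``zero_samples``.
    """

    data: pd.DataFrame
    mode: str = "counts"
    zero_samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate asv_ids: {dups}")
        self.validate()

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def column(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def validate(self) -> None:
        if self.mode == "relative":
            sums = self.data.sum(axis=0)
            for sid, s in sums.items():
                if sid in self.zero_samples:
                    if s != 0:
                        raise ValueError(f"sample {sid!r} flagged zero but sums to {s}")
                elif abs(s - 1.0) > COLUMN_SUM_TOL:
                    raise ValueError(
                        f"relative column {sid!r} sums to {s!r}, not 1 "
                        f"± {COLUMN_SUM_TOL}"
                    )


@dataclass(frozen=True)
class FluxRecord:
    """Particulate carbon and nitrogen flux for one trap collection interval.

    Fluxes and the long-term annual reference means share units
    (mass m^-2 d^-1); only their ratios enter the export-pulse flagging.
    """

    interval_start: dt.date
    interval_end: dt.date
    pc_flux: float
    pn_flux: float
    pc_ref_mean: float
    pn_ref_mean: float

    def __post_init__(self) -> None:
        if self.interval_start > self.interval_end:
            raise ValueError("flux interval_start > interval_end")
        if self.pc_flux < 0 or self.pn_flux < 0:
            raise ValueError("fluxes must be nonnegative")
        if not (self.pc_ref_mean > 0 and self.pn_ref_mean > 0):
            raise ValueError("reference means must be positive")


# ---------------------------------------------------------------------------
# readers


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(str(s).strip())


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read an ASV x sample count table (TSV or CSV, autodetected)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                out.loc[row, col] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric count {cell!r} at row {row!r}, "
                    f"column {col!r}"
                ) from None
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read ASV sequences; the id is the first whitespace token of the header."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata CSV.

    Required columns: ``sample_id``, ``compartment``, ``depth_m``,
    ``date_start``; optional: ``date_end``, ``replicate``, ``n_reads``.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "compartment", "depth_m", "date_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        date_end = None
        if "date_end" in df.columns and isinstance(row.get("date_end"), str) and row["date_end"].strip():
            date_end = _parse_date(row["date_end"])
        replicate = None
        if "replicate" in df.columns and isinstance(row.get("replicate"), str) and row["replicate"].strip():
            replicate = row["replicate"].strip()
        n_reads = None
        if "n_reads" in df.columns and isinstance(row.get("n_reads"), str) and row["n_reads"].strip():
            n_reads = int(float(row["n_reads"]))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                compartment=str(row["compartment"]).strip().lower(),
                depth_m=float(row["depth_m"]),
                date_start=_parse_date(row["date_start"]),
                date_end=date_end,
                replicate=replicate,
                n_reads=n_reads,
            )
        )
    return records


def read_flux(path: str | Path) -> list[FluxRecord]:
    """Read a flux CSV with interval_start, interval_end, pc_flux, pn_flux
    and either per-row or constant pc_ref_mean / pn_ref_mean columns."""
    df = pd.read_csv(path)
    required = {"interval_start", "interval_end", "pc_flux", "pn_flux",
                "pc_ref_mean", "pn_ref_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing flux columns {sorted(missing)}")
    return [
        FluxRecord(
            interval_start=_parse_date(row["interval_start"]),
            interval_end=_parse_date(row["interval_end"]),
            pc_flux=float(row["pc_flux"]),
            pn_flux=float(row["pn_flux"]),
            pc_ref_mean=float(row["pc_ref_mean"]),
            pn_ref_mean=float(row["pn_ref_mean"]),
        )
        for _, row in df.iterrows()
    ]


def load_dataset(
    counts_path: str | Path,
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> tuple[AbundanceMatrix, list[AsvRecord], list[SampleRecord]]:
    """Load and cross-validate a (counts, sequences, metadata) triple.

    Every ASV id in the count table must have a FASTA sequence and every sample
    column a metadata row (hard errors naming the offending id). FASTA entries
    not referenced by the table are dropped with a logged warning.
    """
    counts = read_counts_table(counts_path)
    seqs = read_fasta(fasta_path)
    samples = read_metadata(metadata_path)

    missing_seq = [a for a in counts.index if a not in seqs]
    if missing_seq:
        raise ValueError(
            f"count table references ASVs with no FASTA sequence: {missing_seq}"
        )
    by_id = {s.sample_id: s for s in samples}
    missing_meta = [c for c in counts.columns if c not in by_id]
    if missing_meta:
        raise ValueError(
            f"count table references samples with no metadata row: {missing_meta}"
        )
    extra = sorted(set(seqs) - set(counts.index))
    if extra:
        logger.warning(
            "dropping %d FASTA records not referenced by the count table: %s",
            len(extra), extra[:10],
        )
    asvs = [AsvRecord(a, seqs[a]) for a in counts.index]
    used_samples = [by_id[c] for c in counts.columns]
    return AbundanceMatrix(counts, mode="counts"), asvs, used_samples


# ---------------------------------------------------------------------------
# transforms and writers


def to_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Column-normalize a count matrix to per-sample relative abundances.

    All-zero samples are preserved as zero and flagged in ``zero_samples``
    rather than raising. Idempotent on relative matrices.
    """
    if m.mode == "relative":
        return AbundanceMatrix(m.data.copy(), mode="relative",
                               zero_samples=m.zero_samples)
    sums = m.data.sum(axis=0)
    zero = frozenset(str(s) for s in sums.index[sums == 0])
    safe = sums.replace(0, 1.0)
    rel = m.data / safe
    return AbundanceMatrix(rel, mode="relative", zero_samples=zero)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results(obj, path: str | Path) -> Path:
    """Write any pipeline product to disk.

    Tables (anything exposing ``to_frame()`` or a :class:`pandas.DataFrame`)
    go to TSV with a deterministic column order; fit objects, dicts and
    dataclasses go to JSON. Returns the path written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = None
    if isinstance(obj, pd.DataFrame):
        frame = obj
    elif hasattr(obj, "to_frame") and callable(obj.to_frame):
        frame = obj.to_frame()
    if frame is not None:
        frame.to_csv(path, sep="\t", index=False)
        return path
    if hasattr(obj, "to_dict") and callable(obj.to_dict):
        payload = obj.to_dict()
    else:
        payload = obj
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_counts_table(m: AbundanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.data.rename_axis("asv_id").to_csv(path, sep="\t")
    return path


def write_fasta(asvs: Iterable[AsvRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a in asvs:
            fh.write(f">{a.asv_id}\n{a.dna_sequence}\n")
    return path


def write_metadata(samples: Iterable[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        rows.append({
            "sample_id": s.sample_id,
            "compartment": s.compartment,
            "depth_m": s.depth_m,
            "date_start": s.date_start.isoformat(),
            "date_end": s.date_end.isoformat() if s.date_end else "",
            "replicate": s.replicate or "",
            "n_reads": "" if s.n_reads is None else s.n_reads,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_flux(flux: Iterable[FluxRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in flux:
        rows.append({
            "interval_start": f.interval_start.isoformat(),
            "interval_end": f.interval_end.isoformat(),
            "pc_flux": f.pc_flux,
            "pn_flux": f.pn_flux,
            "pc_ref_mean": f.pc_ref_mean,
            "pn_ref_mean": f.pn_ref_mean,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
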