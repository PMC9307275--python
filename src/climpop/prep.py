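"""Record inclusion rules and standardized annual population growth rates.

Abundance records enter the analysis only if they hold at least ``min_years``
*consecutive* annual abundance values inside the weather window (default
1979-2013).  A record whose years break into several consecutive runs is split
into one block per run (each judged against ``min_years`` on its own).  Records
dominated by zeros — more than 32% zeros AND at least one consecutive pair of
zeros — are removed.  The growth rate is the forward log ratio of (abundance+1)
so that zero counts are representable and rates are scale-comparable across
records measured in different units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "AbundanceRecord",
    "GrowthRateSeries",
    "filter_records",
    "zero_filter",
    "growth_rates",
    "prepare_records",
    "records_from_frame",
]


@dataclass
class AbundanceRecord:
    """One population abundance time series with metadata and QC state."""

    record_id: str
    species: str
    biome: str
    lat: float
    lon: float
    years: np.ndarray
    abundance: np.ndarray
    qc_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.years.shape != self.abundance.shape:
            raise InvalidArgumentError("years and abundance lengths differ")
        if np.any(self.abundance < 0):
            raise InvalidArgumentError("abundance must be non-negative")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def is_consecutive(self) -> bool:
        return self.years.size > 0 and bool(np.all(np.diff(self.years) == 1))


@dataclass
class GrowthRateSeries:
    """Annual growth rates r_t for one record; length = len(abundance) - 1."""

    record_id: str
    years: np.ndarray   # year t of each rate (forward convention: t -> t+1)
    r: np.ndarray
    n_years: int        # record length N in years (before differencing)


def _consecutive_runs(years):
    """Split a sorted integer year vector into maximal consecutive runs."""
    runs, start = [], 0
    for i in range(1, len(years) + 1):
        if i == len(years) or years[i] != years[i - 1] + 1:
            runs.append((start, i))
            start = i
    return runs


def filter_records(records, min_years=10, window=(1979, 2013), qc_log=None):
    """Window-clip, block-split and length-filter abundance records.

    Each maximal run of consecutive years (within the window) with at least
    ``min_years`` values becomes its own record; blocks get suffixed ids
    (``<id>_b1``, ``<id>_b2``, ...) only when a record actually splits.
    ``qc_log`` (optional list) collects dicts describing every dropped
    record/block and the rule that dropped it.
    """
    lo, hi = window
    out = []
    for rec in records:
        order = np.argsort(rec.years)
        years = rec.years[order]
        abund = rec.abundance[order]
        keep = (years >= lo) & (years <= hi)
        if not keep.any():
            if qc_log is not None:
                qc_log.append({"record_id": rec.record_id, "rule": "window",
                               "detail": f"no years in {lo}-{hi}"})
            continue
        years, abund = years[keep], abund[keep]
        runs = _consecutive_runs(years)
        long_runs = [(a, b) for a, b in runs if b - a >= min_years]
        for a, b in runs:
            if b - a < min_years and qc_log is not None:
                qc_log.append({
                    "record_id": rec.record_id, "rule": "min_years",
                    "detail": f"block {years[a]}-{years[b - 1]} has "
                              f"{b - a} < {min_years} years"})
        multi = len(long_runs) > 1
        for k, (a, b) in enumerate(long_runs, start=1):
            rid = f"{rec.record_id}_b{k}" if multi else rec.record_id
            out.append(replace(
                rec, record_id=rid, years=years[a:b], abundance=abund[a:b],
                qc_flags=rec.qc_flags + ([f"split_block_{k}"] if multi else []),
            ))
    return out


def zero_filter(record, max_zero_prop=0.32, require_consecutive=True):
    """True if the record is kept.

    Dropped iff the zero proportion exceeds ``max_zero_prop`` AND (by default)
    at least one pair of adjacent zeros occurs; with
    ``require_consecutive=False`` the proportion alone decides.
    """
    zeros = record.abundance == 0
    prop = zeros.mean() if zeros.size else 0.0
    has_consec = bool(np.any(zeros[:-1] & zeros[1:]))
    if prop > max_zero_prop:
        if has_consec or not require_consecutive:
            return False
        record.qc_flags.append("high_zero_prop_no_consecutive")
    return True


def growth_rates(record, convention="forward") -> GrowthRateSeries:
    """Standardized proportional growth rates r_t = ln((X_{t+1}+1)/(X_t+1)).

    The +1 transform keeps zero abundances representable; the log ratio makes
    rates comparable across records measured in different units.  The sum of
    rates telescopes to ln((X_T+1)/(X_1+1)).  ``convention='forward'`` pairs
    r_t with the weather of year t (year of the first abundance of the pair);
    ``'backward'`` labels the rate with the later year instead.
    """
    if record.n_years < 2:
        raise InvalidArgumentError("need at least 2 years for growth rates")
    if not record.is_consecutive:
        raise InvalidStateError(
            f"record {record.record_id}: years not consecutive — "
            "run filter_records first")
    logx = np.log(record.abundance + 1.0)
    r = np.diff(logx)
    if convention == "forward":
        yrs = record.years[:-1]
    elif convention == "backward":
        yrs = record.years[1:]
    else:
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    return GrowthRateSeries(record_id=record.record_id, years=yrs, r=r,
                            n_years=record.n_years)


def prepare_records(records, min_years=10, window=(1979, 2013),
                    max_zero_prop=0.32, require_consecutive_zeros=True):
    """filter_records + zero_filter; returns (kept_records, qc_frame)."""
    qc = []
    blocks = filter_records(records, min_years=min_years, window=window,
                            qc_log=qc)
    kept = []
    for rec in blocks:
        if zero_filter(rec, max_zero_prop=max_zero_prop,
                       require_consecutive=require_consecutive_zeros):
            kept.append(rec)
        else:
            qc.append({"record_id": rec.record_id, "rule": "zero_filter",
                       "detail": f"zero proportion "
                                 f"{(rec.abundance == 0).mean():.3f} with "
                                 f"consecutive zeros"})
    qc_frame = pd.DataFrame(qc, columns=["record_id", "rule", "detail"])
    return kept, qc_frame


def records_from_frame(df: pd.DataFrame):
    """Build AbundanceRecord objects from a long table
    (record_id, species, biome, lat, lon, year, abundance)."""
    recs = []
    for rid, grp in df.groupby("record_id", sort=True):
        grp = grp.sort_values("year")
        recs.append(AbundanceRecord(
            record_id=str(rid),
            species=grp["species"].iloc[0],
            biome=str(grp["biome"].iloc[0]),
            lat=float(grp["lat"].iloc[0]) if "lat" in grp else np.nan,
            lon=float(grp["lon"].iloc[0]) if "lon" in grp else np.nan,
            years=grp["year"].to_numpy(),
            abundance=grp["abundance"].to_numpy(),
        ))
    return recs
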