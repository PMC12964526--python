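"""Per-scan ion-count estimation and time-window isotopologue ratios.

The ion-count estimate converts a peak's signal-to-noise ratio into the
number of ions observed per scan,

    N_IO = (S/N) * (C_N / z) * sqrt(R_N / R) * sqrt(mu),

with C_N an empirical noise constant (default 3), z the charge, R_N a
reference resolution (default 240 000), R the nominal resolution and mu the
number of microscans.  Isotopologue ratios are ratios of summed ion counts
over a common scan window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ProcessingError, ValidationError
from .scan_io import ScanObservation

__all__ = [
    "IonCountSeries",
    "RatioResult",
    "ions_per_scan",
    "ions_per_scan_array",
    "add_ion_counts",
    "select_window",
    "series_from_frame",
    "window_ratio",
]


def ions_per_scan_array(
    intensity,
    peak_noise,
    resolution,
    microscans,
    charge=1,
    c_n: float = 3.0,
    r_n: float = 240000.0,
):
    """Vectorised ion-count estimate; inputs broadcast like numpy arrays."""
    if c_n <= 0 or r_n <= 0:
        raise ValidationError("c_n and r_n must be > 0")
    peak_noise = np.asarray(peak_noise, dtype=float)
    if np.any(peak_noise <= 0):
        raise ValidationError("peak_noise must be > 0 (division by zero)")
    s_to_n = np.asarray(intensity, dtype=float) / peak_noise
    return (
        s_to_n
        * (c_n / np.asarray(charge, dtype=float))
        * np.sqrt(r_n / np.asarray(resolution, dtype=float))
        * np.sqrt(np.asarray(microscans, dtype=float))
    )


def ions_per_scan(
    obs: ScanObservation, c_n: float = 3.0, r_n: float = 240000.0
) -> float:
    """Estimated number of ions observed in one scan for one isotopologue."""
    return float(
        ions_per_scan_array(
            obs.intensity,
            obs.peak_noise,
            obs.resolution,
            obs.microscans,
            obs.charge,
            c_n=c_n,
            r_n=r_n,
        )
    )


def add_ion_counts(
    frame: pd.DataFrame, c_n: float = 3.0, r_n: float = 240000.0
) -> pd.DataFrame:
    """Return a copy of a scan frame with an ``n_io`` ion-count column."""
    out = frame.copy()
    out["n_io"] = ions_per_scan_array(
        frame["intensity"].to_numpy(),
        frame["peak_noise"].to_numpy(),
        frame["resolution"].to_numpy(),
        frame["microscans"].to_numpy(),
        frame["charge"].to_numpy() if "charge" in frame.columns else 1,
        c_n=c_n,
        r_n=r_n,
    )
    return out


def select_window(frame: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Restrict observations to times in the half-open interval [start, end)."""
    start, end = window
    if start >= end:
        raise ValidationError(f"window start {start} must precede end {end}")
    selected = frame[(frame["time_min"] >= start) & (frame["time_min"] < end)]
    if selected.empty:
        raise ProcessingError(f"no scans fall inside window [{start}, {end}) min")
    return selected


@dataclass(frozen=True)
class IonCountSeries:
    """Per-scan ion counts of one isotopologue over one time window."""

    isotopologue_label: str
    scans: np.ndarray
    counts: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.scans) != len(self.counts):
            raise ValidationError("scans and counts must have equal length")
        if np.any(np.asarray(self.counts) < 0):
            raise ValidationError("ion counts must be >= 0")


@dataclass(frozen=True)
class RatioResult:
    """A summed-count isotopologue ratio with its standard error."""

    numerator_label: str
    basepeak_label: str
    ratio: float
    sem: float
    n_scans: int


def series_from_frame(
    frame: pd.DataFrame, label: str, window: tuple[float, float]
) -> IonCountSeries:
    """Extract one isotopologue's ion-count series over a window.

    Scans present in the window but missing a row for this isotopologue
    contribute zero counts (an undetected peak is zero ions, not missing
    data).
    """
    windowed = select_window(frame, window)
    scans = np.sort(windowed["scan"].unique())
    rows = windowed[windowed["label"] == label]
    counts = (
        rows.groupby("scan")["n_io"].sum().reindex(scans, fill_value=0.0).to_numpy()
    )
    return IonCountSeries(label, scans.astype(int), counts, window)


def window_ratio(
    series_i: IonCountSeries,
    series_base: IonCountSeries,
    sem_method: str = "per_scan",
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> RatioResult:
    """Summed-count ratio of an isotopologue to the base peak over a window.

    The point estimate is sum(counts_i) / sum(counts_base).  Its standard
    error is, by default, the standard error of the mean of per-scan ratios;
    ``sem_method="bootstrap"`` resamples scans instead.
    """
    if series_i.window != series_base.window or not np.array_equal(
        series_i.scans, series_base.scans
    ):
        raise ValidationError("numerator and basepeak series cover different scans")
    total_base = float(series_base.counts.sum())
    if total_base <= 0:
        raise ProcessingError(
            f"basepeak {series_base.isotopologue_label!r} has zero summed counts"
        )
    ratio = float(series_i.counts.sum()) / total_base
    n_scans = len(series_i.scans)

    if sem_method == "per_scan":
        mask = series_base.counts > 0
        per_scan = series_i.counts[mask] / series_base.counts[mask]
        if len(per_scan) < 2:
            sem = 0.0
        else:
            sem = float(np.std(per_scan, ddof=1) / np.sqrt(len(per_scan)))
    elif sem_method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng()
        indices = rng.integers(0, n_scans, size=(n_boot, n_scans))
        boot_i = series_i.counts[indices].sum(axis=1)
        boot_base = series_base.counts[indices].sum(axis=1)
        valid = boot_base > 0
        sem = float(np.std(boot_i[valid] / boot_base[valid], ddof=1))
    else:
        raise ValidationError(f"unknown sem_method {sem_method!r}")
    return RatioResult(
        series_i.isotopologue_label,
        series_base.isotopologue_label,
        ratio,
        sem,
        n_scans,
    )
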