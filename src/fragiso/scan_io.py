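"""Scan-table and results I/O plus run configuration.

Scan tables follow the tab-separated export convention of vendor
isotopologue extraction tools (one row per scan x isotopologue with
intensity, peak noise, resolution and microscans).  The reader also accepts
comma-separated files and matches headers case-insensitively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "ScanObservation",
    "ScanTable",
    "RunConfig",
    "EaIrmsRecord",
    "read_scan_table",
    "write_scan_table",
    "write_results_table",
    "read_results_table",
    "read_standards_table",
    "write_standards_table",
]

#: canonical column -> accepted header spellings (lower-cased, punctuation-free)
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "scan": ("scan", "scanno", "scannumber", "scanindex"),
    "time_min": ("time", "timemin", "rt", "retentiontime"),
    "label": ("isotopolog", "isotopologue", "label"),
    "intensity": ("intensity", "intensities", "s"),
    "peak_noise": ("peaknoise", "noise"),
    "resolution": ("resolution",),
    "microscans": ("microscans", "microscan"),
}
_OPTIONAL_ALIASES: dict[str, tuple[str, ...]] = {
    "charge": ("charge", "z"),
    "source_id": ("sourceid", "source", "filename", "file"),
}
_MANDATORY = ("scan", "time_min", "label", "intensity", "peak_noise", "resolution", "microscans")
_NUMERIC = ("scan", "time_min", "intensity", "peak_noise", "resolution", "microscans")

RESULT_COLUMNS = (
    "fragment",
    "element",
    "delta_permil",
    "sigma_permil",
    "ci95_permil",
    "n",
    "mode",
)


@dataclass(frozen=True)
class ScanObservation:
    """One scan's record for one monitored isotopologue."""

    source_id: str
    scan_index: int
    time_min: float
    isotopologue_label: str
    intensity: float
    peak_noise: float
    resolution: float
    microscans: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.scan_index < 1:
            raise ValidationError(f"scan_index must be >= 1, got {self.scan_index}")
        if self.intensity < 0:
            raise ValidationError(f"intensity must be >= 0, got {self.intensity}")
        if self.peak_noise <= 0:
            raise ValidationError(f"peak_noise must be > 0, got {self.peak_noise}")
        if self.resolution <= 0:
            raise ValidationError(f"resolution must be > 0, got {self.resolution}")
        if self.microscans < 1:
            raise ValidationError(f"microscans must be >= 1, got {self.microscans}")
        if self.charge < 1:
            raise ValidationError(f"charge must be >= 1, got {self.charge}")


class ScanTable(Sequence):
    """A validated scan table: a DataFrame plus the rejected-row count.

    Iterating yields :class:`ScanObservation` records; the underlying frame
    is available as :attr:`frame` for vectorised processing.
    """

    def __init__(self, frame: pd.DataFrame, n_rejected: int = 0) -> None:
        self.frame = frame.reset_index(drop=True)
        self.n_rejected = int(n_rejected)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, index):
        if isinstance(index, slice):
            return [self[i] for i in range(*index.indices(len(self)))]
        row = self.frame.iloc[index]
        return ScanObservation(
            source_id=str(row["source_id"]),
            scan_index=int(row["scan"]),
            time_min=float(row["time_min"]),
            isotopologue_label=str(row["label"]),
            intensity=float(row["intensity"]),
            peak_noise=float(row["peak_noise"]),
            resolution=float(row["resolution"]),
            microscans=int(row["microscans"]),
            charge=int(row["charge"]),
        )

    def __iter__(self) -> Iterator[ScanObservation]:
        for i in range(len(self)):
            yield self[i]


def _normalise(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _detect_sep(path: Path) -> str:
    with open(path) as handle:
        header = handle.readline()
    return "\t" if "\t" in header else ","


def read_scan_table(path, catalog=None) -> ScanTable:
    """Read a delimited scan table, validating columns and numeric cells.

    When ``catalog`` (an iterable of IsotopologueSpec) is given, rows whose
    isotopologue label is not in the catalog are dropped with a warning
    reporting the count.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    rename: dict[str, str] = {}
    for column in frame.columns:
        key = _normalise(column)
        for canonical, aliases in {**_COLUMN_ALIASES, **_OPTIONAL_ALIASES}.items():
            if key in aliases:
                rename[column] = canonical
    frame = frame.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    if "source_id" not in frame.columns:
        frame["source_id"] = path.stem
    if "charge" not in frame.columns:
        frame["charge"] = "1"

    for column in (*_NUMERIC, "charge"):
        numeric = pd.to_numeric(frame[column], errors="coerce")
        bad = numeric.isna() & frame[column].notna()
        if bad.any() or frame[column].isna().any():
            row = int((bad | frame[column].isna()).idxmax()) + 2  # 1-based + header
        else:
            row = None
        if row is not None:
            raise ValidationError(
                f"{path.name}: non-numeric value in column {column!r} at line {row}"
            )
        frame[column] = numeric
    frame["label"] = frame["label"].astype(str)

    n_rejected = 0
    if catalog is not None:
        known = {spec.label for spec in catalog}
        keep = frame["label"].isin(known)
        n_rejected = int((~keep).sum())
        if n_rejected:
            warnings.warn(
                f"{path.name}: rejected {n_rejected} row(s) with unknown "
                f"isotopologue labels",
                stacklevel=2,
            )
            frame = frame[keep]
    frame = frame.sort_values(["source_id", "scan"], kind="stable")
    return ScanTable(frame, n_rejected)


def write_scan_table(frame: pd.DataFrame, path) -> None:
    """Write a scan frame in the tab-separated export dialect."""
    out = frame.rename(
        columns={
            "time_min": "time.min",
            "label": "isotopolog",
            "peak_noise": "peakNoise",
            "source_id": "sourceID",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_results_table(delta_values: Iterable, path) -> None:
    """Serialise DeltaValue records as TSV (6-decimal, round-trip stable)."""
    rows = [
        {
            "fragment": dv.fragment,
            "element": dv.element,
            "delta_permil": dv.delta,
            "sigma_permil": dv.sigma,
            "ci95_permil": dv.ci95,
            "n": dv.n,
            "mode": dv.mode,
        }
        for dv in delta_values
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_results_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"results table {path}: missing column(s): {', '.join(missing)}"
        )
    return frame


@dataclass(frozen=True)
class EaIrmsRecord:
    """One bulk delta determination of an in-house standard."""

    standard_id: str
    element: str
    delta_bulk: float
    sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def write_standards_table(records: Iterable, path) -> None:
    """Write standard definitions (id, fragment, element, bulk shift, sd)."""
    rows = [
        {
            "standard_id": r.standard_id,
            "fragment": r.labeled_fragment,
            "element": r.labeled_element,
            "delta_bulk_shift_permil": r.delta_bulk_shift,
            "sd_permil": r.sd,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "standard_id",
            "fragment",
            "element",
            "delta_bulk_shift_permil",
            "sd_permil",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_standards_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = ["standard_id", "fragment", "element", "delta_bulk_shift_permil"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"standards table {path}: missing column(s): {', '.join(missing)}"
        )
    if "sd_permil" not in frame.columns:
        frame["sd_permil"] = 0.0
    return frame


@dataclass(frozen=True)
class RunConfig:
    """Processing configuration for one measurement sequence."""

    mode: str = "lc_blocks"
    data_window_min: float = 15.0
    switch_discard_min: float = 3.0
    block_duration_min: float = 18.0
    agc_target: float = 3.0e6
    c_n: float = 3.0
    r_n: float = 240000.0
    t_alpha: float = 0.05
    sem_method: str = "per_scan"
    ci_estimator: str = "eq7"
    roles: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("direct_infusion", "lc_blocks"):
            raise ConfigError(
                f"mode: expected 'direct_infusion' or 'lc_blocks', got {self.mode!r}"
            )
        for key in ("data_window_min", "switch_discard_min", "block_duration_min"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key}: must be > 0, got {getattr(self, key)}")
        if self.switch_discard_min >= self.block_duration_min:
            raise ConfigError(
                "switch_discard_min must be smaller than block_duration_min"
            )
        if self.c_n <= 0 or self.r_n <= 0:
            raise ConfigError("constants: c_n and r_n must be > 0")
        if not 0.0 < self.t_alpha < 1.0:
            raise ConfigError(f"t_alpha: must lie in (0, 1), got {self.t_alpha}")
        if self.sem_method not in ("per_scan", "bootstrap"):
            raise ConfigError(f"sem_method: unknown method {self.sem_method!r}")
        if self.ci_estimator not in ("eq7", "replicate_sd", "propagated"):
            raise ConfigError(f"ci_estimator: unknown estimator {self.ci_estimator!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        constants = data.pop("constants", {}) or {}
        kwargs: dict = {}
        for key in (
            "mode",
            "data_window_min",
            "switch_discard_min",
            "block_duration_min",
            "agc_target",
            "t_alpha",
            "sem_method",
            "ci_estimator",
        ):
            if key in data:
                kwargs[key] = data.pop(key)
        for key, alias in (("c_n", "C_N"), ("r_n", "R_N")):
            if key in constants:
                kwargs[key] = constants[key]
            elif alias in constants:
                kwargs[key] = constants[alias]
            elif key in data:
                kwargs[key] = data.pop(key)
        if "roles" in data:
            roles = data.pop("roles")
            kwargs["roles"] = tuple((str(s), str(r)) for s, r in roles)
        if data:
            unknown = ", ".join(sorted(map(str, data)))
            raise ConfigError(f"run config: unknown key(s): {unknown}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, Mapping):
            raise ConfigError(f"run config {path}: expected a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "data_window_min": self.data_window_min,
            "switch_discard_min": self.switch_discard_min,
            "block_duration_min": self.block_duration_min,
            "agc_target": self.agc_target,
            "constants": {"c_n": self.c_n, "r_n": self.r_n},
            "t_alpha": self.t_alpha,
            "sem_method": self.sem_method,
            "ci_estimator": self.ci_estimator,
            "roles": [list(pair) for pair in self.roles],
        }

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
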