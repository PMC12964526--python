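"""Synthetic scan-table generation with the statistical structure the
processing chain assumes.

Per scan, the expected number of detected fragment ions is the AGC target
times a transfer efficiency, split between F92 and F99 and distributed over
the six monitored isotopologues according to the stochastic abundance model
and the configured true delta shifts.  Counts are drawn Poisson, a smooth
multiplicative spray drift (common to all isotopologues, so it cancels in
ratios) is applied, and intensities are written by inverting the ion-count
estimate at constant peak noise - so the processing chain recovers the drawn
counts to machine precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import SMX, MoleculeDef, natural_per_atom_ratio, smx_catalog
from .errors import ConfigError, ValidationError
from .scan_io import EaIrmsRecord
from .calibration import StandardDefinition

__all__ = [
    "SimulationConfig",
    "TrueState",
    "DegradationScenario",
    "rayleigh_shift",
    "simulate_scan_table",
    "simulate_bracketed_sequence",
    "simulate_standard_series",
    "simulate_degradation",
]

Position = tuple[str, str]  # (fragment, element)


def parse_position_key(key: str) -> Position:
    """Parse a config key like ``"F99.N"`` into (fragment, element)."""
    try:
        fragment, element = key.split(".")
    except ValueError:
        raise ConfigError(
            f"position key {key!r}: expected '<fragment>.<element>'"
        ) from None
    return fragment, element


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for synthetic scan tables."""

    seed: int = 0
    agc_target: float = 3.0e6
    transfer_efficiency: float = 0.5
    scan_period_s: float = 2.0
    duration_min: float = 18.0
    fragment_split: float = 0.5  # fraction of fragment ions going to F92
    true_deltas: Mapping[Position, float] = field(default_factory=dict)
    response: Mapping[Position, tuple[float, float]] = field(default_factory=dict)
    drift_rel_sd: float = 0.05
    noise_floor: float = 1000.0
    resolution: float = 90000.0
    microscans: int = 10
    charge: int = 1
    c_n: float = 3.0
    r_n: float = 240000.0

    def __post_init__(self) -> None:
        if self.agc_target <= 0:
            raise ConfigError("agc_target must be > 0")
        if not 0.0 < self.transfer_efficiency <= 1.0:
            raise ConfigError("transfer_efficiency must lie in (0, 1]")
        if not 0.0 < self.fragment_split < 1.0:
            raise ConfigError("fragment_split must lie in (0, 1)")
        if self.drift_rel_sd < 0:
            raise ConfigError("drift_rel_sd must be >= 0")
        if self.scan_period_s <= 0 or self.duration_min <= 0:
            raise ConfigError("scan_period_s and duration_min must be > 0")
        if self.noise_floor <= 0:
            raise ConfigError("noise_floor must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        for key in ("true_deltas", "response"):
            raw = data.get(key)
            if raw:
                parsed = {}
                for position, value in raw.items():
                    pos = (
                        parse_position_key(position)
                        if isinstance(position, str)
                        else tuple(position)
                    )
                    if key == "response":
                        if isinstance(value, Mapping):
                            value = (
                                float(value.get("slope", 1.0)),
                                float(value.get("intercept", 0.0)),
                            )
                        else:
                            value = (float(value[0]), float(value[1]))
                    else:
                        value = float(value)
                    parsed[pos] = value
                data[key] = parsed
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"simulation config: unknown key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def measured_delta(self, position: Position) -> float:
        """True delta pushed through the instrument response (delta space)."""
        slope, intercept = self.response.get(position, (1.0, 0.0))
        return slope * self.true_deltas.get(position, 0.0) + intercept


@dataclass(frozen=True)
class TrueState:
    """Ground truth serialised alongside every synthetic dataset."""

    seed: int
    true_deltas: Mapping[Position, float]
    response: Mapping[Position, tuple[float, float]]
    config: Mapping

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "true_deltas": {f"{f}.{e}": v for (f, e), v in self.true_deltas.items()},
            "response": {
                f"{f}.{e}": list(v) for (f, e), v in self.response.items()
            },
            "config": dict(self.config),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TrueState":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            seed=payload["seed"],
            true_deltas={
                parse_position_key(k): v for k, v in payload["true_deltas"].items()
            },
            response={
                parse_position_key(k): tuple(v)
                for k, v in payload["response"].items()
            },
            config=payload["config"],
        )


def _drift_profile(
    n_scans: int, rel_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative random walk with unit mean and ~rel_sd spread."""
    if rel_sd == 0 or n_scans < 2:
        return np.ones(n_scans)
    walk = np.cumsum(rng.standard_normal(n_scans))
    walk -= walk.mean()
    spread = walk.std()
    if spread > 0:
        walk *= math.sqrt(math.log1p(rel_sd**2)) / spread
    return np.exp(walk)


_FRAGMENTS = ("F92", "F99")


def _isotopologue_expectations(
    config: SimulationConfig, true_deltas: Mapping[Position, float]
) -> dict[str, float]:
    """Expected ions per scan per isotopologue label (before drift/Poisson)."""
    total = config.agc_target * config.transfer_efficiency
    catalog = smx_catalog()
    expectations: dict[str, float] = {}
    for fragment in _FRAGMENTS:
        share = (
            config.fragment_split if fragment == "F92" else 1.0 - config.fragment_split
        )
        specs = [s for s in catalog if s.fragment_name == fragment]
        base = next(s for s in specs if not s.substitutions)
        ratios: dict[str, float] = {}
        for spec in specs:
            if not spec.substitutions:
                continue
            (element,) = spec.substitutions
            n_atoms = spec.formula.n(element)
            slope, intercept = config.response.get((fragment, element), (1.0, 0.0))
            delta_meas = slope * true_deltas.get((fragment, element), 0.0) + intercept
            ratios[spec.label] = (
                n_atoms
                * natural_per_atom_ratio(element)
                * (1.0 + delta_meas / 1000.0)
            )
        base_share = 1.0 / (1.0 + sum(ratios.values()))
        expectations[base.label] = total * share * base_share
        for label, ratio in ratios.items():
            expectations[label] = total * share * base_share * ratio
    return expectations


def simulate_scan_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    start_min: float = 0.0,
    duration_min: float | None = None,
    true_deltas: Mapping[Position, float] | None = None,
    source_id: str = "sim",
    first_scan: int = 1,
) -> tuple[pd.DataFrame, TrueState]:
    """Generate one contiguous stretch of synthetic scans.

    Returns the scan frame (canonical columns, ready for the processing
    chain) and the ground-truth state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if duration_min is None:
        duration_min = config.duration_min
    if true_deltas is None:
        true_deltas = dict(config.true_deltas)
    n_scans = int(round(duration_min * 60.0 / config.scan_period_s))
    if n_scans < 1:
        raise ValidationError("duration too short for a single scan")
    times = start_min + np.arange(n_scans) * config.scan_period_s / 60.0
    drift = _drift_profile(n_scans, config.drift_rel_sd, rng)
    expectations = _isotopologue_expectations(config, true_deltas)

    # intensity = N_IO * noise * z / (C_N * sqrt(R_N/R) * sqrt(mu))
    inverse_gain = (
        config.noise_floor
        * config.charge
        / (
            config.c_n
            * math.sqrt(config.r_n / config.resolution)
            * math.sqrt(config.microscans)
        )
    )
    pieces = []
    for label, mean_ions in expectations.items():
        lam = mean_ions * drift
        if np.any(lam <= 0):
            raise ValidationError(f"non-positive expected count for {label!r}")
        counts = rng.poisson(lam).astype(float)
        pieces.append(
            pd.DataFrame(
                {
                    "source_id": source_id,
                    "scan": np.arange(first_scan, first_scan + n_scans),
                    "time_min": times,
                    "label": label,
                    "intensity": counts * inverse_gain,
                    "peak_noise": config.noise_floor,
                    "resolution": config.resolution,
                    "microscans": config.microscans,
                    "charge": config.charge,
                }
            )
        )
    frame = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["scan", "label"], kind="stable")
        .reset_index(drop=True)
    )
    truth = TrueState(
        seed=config.seed,
        true_deltas=dict(true_deltas),
        response=dict(config.response),
        config={
            "agc_target": config.agc_target,
            "transfer_efficiency": config.transfer_efficiency,
            "scan_period_s": config.scan_period_s,
            "fragment_split": config.fragment_split,
            "drift_rel_sd": config.drift_rel_sd,
            "noise_floor": config.noise_floor,
            "resolution": config.resolution,
            "microscans": config.microscans,
        },
    )
    return frame, truth


def simulate_bracketed_sequence(
    config: SimulationConfig,
    n_reference: int = 5,
    n_sample: int = 4,
    block_duration_min: float = 18.0,
    sample_deltas: Mapping[Position, float] | None = None,
    reference_deltas: Mapping[Position, float] | None = None,
    rng: np.random.Generator | None = None,
    source_id: str = "sequence",
) -> tuple[pd.DataFrame, TrueState]:
    """Alternating reference/sample blocks on one timeline (reference first).

    The reference (working standard) is generated at delta = 0 by default;
    the sample blocks use ``sample_deltas`` (default: config.true_deltas).
    """
    if n_reference != n_sample + 1:
        raise ValidationError(
            f"alternating layout needs n_reference = n_sample + 1, "
            f"got {n_reference} and {n_sample}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sample_deltas is None:
        sample_deltas = dict(config.true_deltas)
    if reference_deltas is None:
        reference_deltas = {}
    frames = []
    truth = None
    first_scan = 1
    for k in range(n_reference + n_sample):
        role_deltas = reference_deltas if k % 2 == 0 else sample_deltas
        frame, block_truth = simulate_scan_table(
            config,
            rng=rng,
            start_min=k * block_duration_min,
            duration_min=block_duration_min,
            true_deltas=role_deltas,
            source_id=source_id,
            first_scan=first_scan,
        )
        first_scan += int(frame["scan"].max()) - first_scan + 1
        frames.append(frame)
        if k % 2 == 1:
            truth = block_truth
    combined = pd.concat(frames, ignore_index=True)
    if truth is None:  # pragma: no cover - layout guarantees a sample block
        truth = TrueState(config.seed, dict(sample_deltas), dict(config.response), {})
    return combined, truth


def simulate_standard_series(
    labels: Sequence[Position],
    spike_targets: Sequence[float] = (50.0, 100.0, 200.0),
    ea_sd: float = 0.3,
    n_replicates: int = 5,
    seed: int = 0,
    molecule: MoleculeDef = SMX,
) -> tuple[list[StandardDefinition], list[EaIrmsRecord]]:
    """Generate labeled-standard definitions plus their EA-IRMS records.

    For each labeled position and target fragment enrichment, the true bulk
    shift follows from mass balance (fragment share of the element's atoms);
    EA-IRMS replicates scatter around it with standard deviation ``ea_sd``.
    """
    if any(t <= 0 for t in spike_targets):
        raise ValidationError("spike targets must be positive")
    rng = np.random.default_rng(seed)
    standards: list[StandardDefinition] = []
    records: list[EaIrmsRecord] = []
    letters = string.ascii_uppercase
    for i, (fragment, element) in enumerate(labels):
        n_fragment = molecule.fragment_count(fragment, element)
        if n_fragment == 0:
            raise ValidationError(
                f"no {element} atoms in fragment {fragment!r} of {molecule.name}"
            )
        n_total = molecule.formula.n(element)
        for j, target in enumerate(spike_targets, start=1):
            bulk_true = target * n_fragment / n_total
            replicates = bulk_true + ea_sd * rng.standard_normal(n_replicates)
            bulk_measured = float(replicates.mean())
            standard_id = f"{letters[i]}{j}"
            standards.append(
                StandardDefinition(
                    standard_id=standard_id,
                    labeled_fragment=fragment,
                    labeled_element=element,
                    spike_target_permil=float(target),
                    delta_bulk_shift=bulk_measured,
                    sd=float(replicates.std(ddof=1)) if n_replicates > 1 else 0.0,
                    molecule=molecule,
                )
            )
            records.append(
                EaIrmsRecord(
                    standard_id=standard_id,
                    element=element,
                    delta_bulk=bulk_measured,
                    sd=float(replicates.std(ddof=1)) if n_replicates > 1 else 0.0,
                    n_replicates=n_replicates,
                )
            )
    return standards, records


def rayleigh_shift(epsilon: float, remaining_fraction: float) -> float:
    """Closed-form Rayleigh enrichment of the residual substrate:
    delta shift = epsilon * ln(f)."""
    if not 0.0 < remaining_fraction <= 1.0:
        raise ValidationError(
            f"remaining fraction must lie in (0, 1], got {remaining_fraction}"
        )
    return epsilon * math.log(remaining_fraction)


@dataclass(frozen=True)
class DegradationScenario:
    """True delta trajectories per (fragment, element) over timepoints."""

    timepoints: tuple[float, ...]
    trajectories: Mapping[Position, tuple[float, ...]]

    def __post_init__(self) -> None:
        for position, deltas in self.trajectories.items():
            if len(deltas) != len(self.timepoints):
                raise ValidationError(
                    f"trajectory of {position} has {len(deltas)} values for "
                    f"{len(self.timepoints)} timepoints"
                )
            if not all(math.isfinite(d) for d in deltas):
                raise ValidationError(f"non-finite delta in trajectory of {position}")

    @classmethod
    def from_rayleigh(
        cls,
        timepoints: Sequence[float],
        remaining_fractions: Sequence[float],
        epsilons: Mapping[Position, float],
        initial_deltas: Mapping[Position, float] | None = None,
    ) -> "DegradationScenario":
        """Build trajectories from an enrichment factor per position."""
        if len(remaining_fractions) != len(timepoints):
            raise ValidationError("one remaining fraction per timepoint required")
        initial_deltas = initial_deltas or {}
        trajectories = {
            position: tuple(
                initial_deltas.get(position, 0.0) + rayleigh_shift(eps, f)
                for f in remaining_fractions
            )
            for position, eps in epsilons.items()
        }
        return cls(tuple(timepoints), trajectories)

    def deltas_at(self, index: int) -> dict[Position, float]:
        return {pos: traj[index] for pos, traj in self.trajectories.items()}


def simulate_degradation(
    scenario: DegradationScenario,
    config: SimulationConfig,
    n_reference: int = 5,
    n_sample: int = 4,
    block_duration_min: float = 18.0,
) -> list[tuple[float, pd.DataFrame, TrueState]]:
    """One bracketed sequence per timepoint, with true deltas following the
    scenario trajectories (positions not listed stay at 0)."""
    rng = np.random.default_rng(config.seed)
    out = []
    for index, timepoint in enumerate(scenario.timepoints):
        frame, truth = simulate_bracketed_sequence(
            config,
            n_reference=n_reference,
            n_sample=n_sample,
            block_duration_min=block_duration_min,
            sample_deltas=scenario.deltas_at(index),
            rng=rng,
            source_id=f"t{index}",
        )
        out.append((timepoint, frame, truth))
    return out
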