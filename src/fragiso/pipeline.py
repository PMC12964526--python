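"""End-to-end processing: scan frame -> ion counts -> block ratios ->
bracketed delta shifts with confidence intervals.

The chain mirrors the measurement design: ion counting per scan, summed
isotopologue ratios per usable block window, sample/reference bracketing,
Gaussian error propagation, and replicate aggregation into 95% CIs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bracketing import (
    DeltaValue,
    MeasurementBlock,
    blocks_from_sources,
    combine_bracketed,
    segment_blocks,
)
from .calibration import CalibrationModel, apply_calibration
from .chem import IsotopologueSpec, smx_catalog
from .errors import ProcessingError, ValidationError
from .ion_stats import add_ion_counts, series_from_frame, window_ratio
from .scan_io import RunConfig

__all__ = [
    "ProcessResult",
    "process_run",
    "calibrate_delta_values",
    "sha256_file",
    "make_manifest",
]


@dataclass
class ProcessResult:
    """Aggregated delta shifts plus per-block detail for one sequence."""

    delta_values: list[DeltaValue]
    blocks: list[MeasurementBlock]
    block_deltas: pd.DataFrame

    def by_position(self) -> dict[tuple[str, str], DeltaValue]:
        return {(dv.fragment, dv.element): dv for dv in self.delta_values}


def _label_maps(
    catalog: Iterable[IsotopologueSpec],
) -> tuple[dict[str, str], dict[tuple[str, str], str]]:
    """(fragment -> basepeak label, (fragment, element) -> heavy label)."""
    base: dict[str, str] = {}
    heavy: dict[tuple[str, str], str] = {}
    for spec in catalog:
        if not spec.substitutions:
            base[spec.fragment_name] = spec.label
        else:
            (element,) = spec.substitutions
            heavy[(spec.fragment_name, element)] = spec.label
    return base, heavy


def process_run(
    frame: pd.DataFrame,
    config: RunConfig,
    catalog: Iterable[IsotopologueSpec] | None = None,
    rng: np.random.Generator | None = None,
    reference_id: str = "SMX0",
) -> ProcessResult:
    """Process one measurement sequence into delta shifts per fragment/element.

    The reference (working standard) delta is set to 0 by construction, so
    each reported delta is already the shift vs the bracketing reference.
    """
    catalog = list(catalog) if catalog is not None else smx_catalog()
    base_labels, heavy_labels = _label_maps(catalog)
    present = set(frame["label"].unique())

    counted = add_ion_counts(frame, c_n=config.c_n, r_n=config.r_n)
    if config.mode == "lc_blocks":
        blocks = segment_blocks(counted, config)
    else:
        blocks = blocks_from_sources(counted, config)

    for block in blocks:
        block_frame = counted
        if block.source_id is not None:
            block_frame = counted[counted["source_id"] == block.source_id]
        for fragment, base_label in base_labels.items():
            if base_label not in present:
                continue
            base_series = series_from_frame(
                block_frame, base_label, block.usable_window
            )
            for (frag, element), heavy_label in heavy_labels.items():
                if frag != fragment or heavy_label not in present:
                    continue
                heavy_series = series_from_frame(
                    block_frame, heavy_label, block.usable_window
                )
                block.ratios[(fragment, element)] = window_ratio(
                    heavy_series,
                    base_series,
                    sem_method=config.sem_method,
                    rng=rng,
                )

    sample_blocks = [b for b in blocks if b.role == "sample"]
    reference_blocks = [b for b in blocks if b.role == "reference"]
    if not sample_blocks:
        raise ProcessingError("sequence contains no sample blocks")

    delta_values: list[DeltaValue] = []
    detail_rows = []
    positions = sorted(
        {key for b in blocks for key in b.ratios}, key=lambda k: (k[0], k[1])
    )
    for position in positions:
        try:
            sample_ratios = [b.ratios[position] for b in sample_blocks]
            ref_ratios = [b.ratios[position] for b in reference_blocks]
        except KeyError:
            raise ProcessingError(
                f"isotopologue pair {position} missing from some blocks"
            ) from None
        delta, sigma, ci, block_deltas = combine_bracketed(
            sample_ratios,
            ref_ratios,
            alpha=config.t_alpha,
            estimator=config.ci_estimator,
        )
        fragment, element = position
        delta_values.append(
            DeltaValue(
                fragment=fragment,
                element=element,
                delta=delta,
                sigma=sigma,
                ci95=ci,
                n=len(sample_ratios),
                reference_id=reference_id,
                mode=config.mode,
            )
        )
        for bd in block_deltas:
            detail_rows.append(
                {
                    "fragment": fragment,
                    "element": element,
                    "block_index": bd.block_index,
                    "delta_permil": bd.delta,
                    "sigma_permil": bd.sigma,
                    "r_sample": bd.r_sample,
                    "r_ref_avg": bd.r_ref_avg,
                }
            )
    return ProcessResult(delta_values, blocks, pd.DataFrame(detail_rows))


def calibrate_delta_values(
    delta_values: Iterable[DeltaValue],
    models: Mapping[tuple[str, str], CalibrationModel],
) -> list[DeltaValue]:
    """Map measured delta shifts onto the standard-defined scale.

    Positions without a model pass through unchanged; the CI scales with the
    sigma (1/|slope|).
    """
    out = []
    for dv in delta_values:
        model = models.get((dv.fragment, dv.element))
        if model is None:
            out.append(dv)
            continue
        calibrated, sigma = apply_calibration(model, dv.delta, dv.sigma)
        scale = sigma / dv.sigma if dv.sigma > 0 else 1.0 / abs(model.slope)
        out.append(
            DeltaValue(
                fragment=dv.fragment,
                element=dv.element,
                delta=calibrated,
                sigma=sigma,
                ci95=dv.ci95 * scale,
                n=dv.n,
                reference_id=dv.reference_id,
                mode=dv.mode + "+calibrated",
            )
        )
    return out


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def make_manifest(
    config: Mapping,
    inputs: Mapping[str, str],
    seed: int | None,
    row_counts: Mapping[str, int],
    outputs: Mapping[str, str],
) -> dict:
    """Machine-readable run record: config snapshot, input digests, seed,
    package version, per-stage row counts and output digests."""
    return {
        "package": "fragiso",
        "version": __version__,
        "seed": seed,
        "config": dict(config),
        "inputs": dict(inputs),
        "row_counts": dict(row_counts),
        "outputs": dict(outputs),
    }


def write_manifest(manifest: Mapping, path) -> None:
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
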