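"""Normalized per-region histograms of index maps and their three metrics.

Bin widths follow the study defaults: 0.05e-3 mm^2/s for MD/AD/RD, 0.03 for
FA and 0.08 for MO.  Bins are anchored at the range minimum, left-closed /
right-open with the last bin closed.  Frequencies are normalized by the
number of counted voxels so region size cancels out.  The median is taken
from the raw voxel values (not the binned counts); peak location is the
center of the maximal bin with ties broken toward the lowest bin, and peak
height is that maximal normalized frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core_io import RegionMask
from .indices import INDEX_NAMES, IndexMaps

__all__ = [
    "HistogramSpec",
    "Histogram",
    "HistogramMetrics",
    "DEFAULT_SPECS",
    "default_spec",
    "build_histogram",
    "compute_metrics",
    "region_metrics_table",
]

_MS = 1e-3


@dataclass(frozen=True)
class HistogramSpec:
    """Bin width and value range for one index's histogram."""

    bin_width: float
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if not self.vmax > self.vmin:
            raise ValueError("vmax must exceed vmin")

    @property
    def edges(self) -> np.ndarray:
        # anchored at vmin; the last bin may extend past vmax when the range
        # is not an integer number of widths
        n_bins = int(np.ceil((self.vmax - self.vmin) / self.bin_width - 1e-9))
        return self.vmin + self.bin_width * np.arange(n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


DEFAULT_SPECS: dict[str, HistogramSpec] = {
    "md": HistogramSpec(bin_width=0.05 * _MS, vmin=0.0, vmax=4.0 * _MS),
    "ad": HistogramSpec(bin_width=0.05 * _MS, vmin=0.0, vmax=4.0 * _MS),
    "rd": HistogramSpec(bin_width=0.05 * _MS, vmin=0.0, vmax=4.0 * _MS),
    "fa": HistogramSpec(bin_width=0.03, vmin=0.0, vmax=1.0),
    "mo": HistogramSpec(bin_width=0.08, vmin=-1.0, vmax=1.0),
}


def default_spec(index: str) -> HistogramSpec:
    try:
        return DEFAULT_SPECS[index.lower()]
    except KeyError:
        raise KeyError(f"no default histogram spec for index {index!r}") from None


@dataclass(frozen=True)
class Histogram:
    bin_centers: np.ndarray
    frequencies: np.ndarray  # fractions, sum to 1 when n_counted > 0
    n_counted: int
    n_excluded: int


@dataclass(frozen=True)
class HistogramMetrics:
    median: float
    peak_location: float
    peak_height: float


def _masked_values(index_map: np.ndarray, mask, validity) -> np.ndarray:
    if isinstance(mask, RegionMask):
        mask = mask.mask
    eff = np.asarray(mask).astype(bool)
    if validity is not None:
        eff = eff & np.asarray(validity).astype(bool)
    values = np.asarray(index_map, dtype=float)[eff]
    return values[np.isfinite(values)]


def build_histogram(index_map: np.ndarray, mask, validity,
                    spec: HistogramSpec, max_excluded_fraction: float = 0.05) -> Histogram:
    """Histogram of valid in-mask voxels, normalized by the counted total.

    Out-of-range voxels are excluded and tallied; more than
    ``max_excluded_fraction`` of them indicates a misconfigured range and is
    an error.
    """
    values = _masked_values(index_map, mask, validity)
    if values.size == 0:
        raise ValueError("empty effective mask (mask ∩ validity)")
    in_range = (values >= spec.vmin) & (values <= spec.vmax)
    n_excluded = int((~in_range).sum())
    if n_excluded > max_excluded_fraction * values.size:
        raise ValueError(
            f"{n_excluded}/{values.size} voxels fall outside "
            f"[{spec.vmin}, {spec.vmax}]; histogram range looks misconfigured"
        )
    if n_excluded > 0.01 * values.size:
        warnings.warn(
            f"histogram range covers <99% of in-mask values "
            f"({n_excluded}/{values.size} excluded)", stacklevel=2)
    counted = values[in_range]
    if counted.size == 0:
        raise ValueError("no in-range voxels to histogram")
    counts, _ = np.histogram(counted, bins=spec.edges)
    return Histogram(bin_centers=spec.centers,
                     frequencies=counts / counted.size,
                     n_counted=int(counted.size),
                     n_excluded=n_excluded)


def compute_metrics(values_in_mask: np.ndarray, histogram: Histogram) -> HistogramMetrics:
    """Median from raw values; peak location/height from the histogram."""
    values = np.asarray(values_in_mask, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0 or histogram.n_counted == 0:
        raise ValueError("cannot compute metrics of an empty sample")
    peak_idx = int(np.argmax(histogram.frequencies))  # first max = lowest bin
    return HistogramMetrics(
        median=float(np.median(values)),
        peak_location=float(histogram.bin_centers[peak_idx]),
        peak_height=float(histogram.frequencies[peak_idx]),
    )


def region_metrics_table(index_maps: IndexMaps, masks: dict[str, RegionMask],
                         specs: dict[str, HistogramSpec] | None = None) -> pd.DataFrame:
    """Tidy table of the 3 metrics for every region x index combination.

    Values are in native units (diffusivities in mm^2/s); reporting layers
    rescale for display.
    """
    specs = {**DEFAULT_SPECS, **(specs or {})}
    maps = index_maps.as_dict()
    rows = []
    for label, region in masks.items():
        for index in INDEX_NAMES:
            if index not in maps:
                raise KeyError(f"missing index map '{index}'")
            spec = specs[index]
            hist = build_histogram(maps[index], region, index_maps.valid, spec)
            values = _masked_values(maps[index], region, index_maps.valid)
            values = values[(values >= spec.vmin) & (values <= spec.vmax)]
            metrics = compute_metrics(values, hist)
            for metric_name, value in (("median", metrics.median),
                                       ("peak_location", metrics.peak_location),
                                       ("peak_height", metrics.peak_height)):
                rows.append({"region": label, "index": index,
                             "metric": metric_name, "value": value})
    return pd.DataFrame(rows)
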