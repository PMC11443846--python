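"""End-to-end batch analysis: nuclei, foci, per-nucleus records, outputs.

The pipeline mirrors the standard two-stage design of focus-counting
workflows:

1. **Nucleus detection** (marker channel): a user-chosen background cut-off
   floors the image, Otsu's method splits the remaining histogram, connected
   components are extracted, and components are gated to a pixel-area window
   so that only single nuclei of the wanted cell type survive.
2. **Focus detection** (damage channel): an adaptive Gaussian-C local
   threshold binarizes the whole damage image, the mask is intersected with
   each retained nucleus's pixel set, components are labelled per nucleus,
   and a minimum focus area discards sub-threshold specks.

Each retained nucleus yields one :class:`NucleusRecord` with its focus
count, mean focus area, and total damaged area — nuclei with zero foci are
reported too, so group means over all analysed cells are correct.

A batch run writes the fixed output tree::

    <output_name>/
        Output_images_nucleus/      colour label map per marker image
        Output_images_DNAdamage/    colour label map of detected foci
        Output_images_overlaid/     raw damage image with foci re-coloured
        Quantification.csv          one row per retained nucleus
        Given_parameters.csv        full parameter provenance of the run
        pixel_intensity.csv/.png    pooled marker intensity histogram
        MARKER_size.csv/.png        detected-object size histogram
"""

from __future__ import annotations

import csv
import datetime
import logging
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .batchio import ChannelBatch, GrayImage, write_label_image, write_overlay
from .errors import InvalidInputError, InvalidOutputError, InvalidParameterError
from .regions import Region, filter_by_area, label_components, marker_size_histogram
from .thresholding import (
    adaptive_gaussian_mask,
    batch_intensity_histogram,
    otsu_threshold,
    suggest_cutoff,
)

logger = logging.getLogger(__name__)

#: Output folder name reserved by the application.
RESERVED_OUTPUT_NAME = "Results"

QUANTIFICATION_COLUMNS = [
    "image_name",
    "nucleus_id",
    "nucleus_area_px",
    "foci_count",
    "mean_foci_area_px",
    "total_foci_area_px",
]


@dataclass(frozen=True)
class AnalysisParams:
    """User-entered analysis parameters plus fixed algorithm knobs.

    intensity_cutoff
        Background floor in [0, 255] applied before Otsu on the marker
        channel; pixels below it can never become nucleus foreground.
    marker_area_min / marker_area_max
        Pixel-area window for retained marker objects (single nuclei).
    foci_area_min
        Minimum pixel area of a reported focus (>= 1; 1 keeps everything).
    connectivity
        Pixel adjacency for component labeling, 4 or 8 (default 8).
    block_size / c_offset
        Window size and constant offset of the adaptive Gaussian-C focus
        threshold.
    exclude_edge_nuclei
        Drop nuclei whose bounding box touches the image border (off by
        default; edge cells are conventionally removed by inspection).
    """

    intensity_cutoff: int = 0
    marker_area_min: int = 1
    marker_area_max: int = 10**9
    foci_area_min: int = 1
    connectivity: int = 8
    block_size: int = 11
    c_offset: int = 2
    exclude_edge_nuclei: bool = False

    def validate(self) -> None:
        if not 0 <= self.intensity_cutoff <= 255:
            raise InvalidParameterError(
                f"intensity_cutoff must be in [0, 255], got {self.intensity_cutoff}"
            )
        if self.marker_area_min < 1 or self.marker_area_max < self.marker_area_min:
            raise InvalidParameterError(
                "marker area window invalid: "
                f"[{self.marker_area_min}, {self.marker_area_max}]"
            )
        if self.foci_area_min < 1:
            raise InvalidParameterError(
                f"foci_area_min must be >= 1, got {self.foci_area_min}"
            )
        if self.connectivity not in (4, 8):
            raise InvalidParameterError(
                f"connectivity must be 4 or 8, got {self.connectivity}"
            )
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise InvalidParameterError(
                f"block_size must be odd and >= 3, got {self.block_size}"
            )


@dataclass(frozen=True)
class NucleusRecord:
    """Per-nucleus quantification row of the Quantification CSV."""

    image_name: str
    nucleus_id: int
    nucleus_area: int
    foci_count: int
    mean_foci_area: float  # 0.0 sentinel when foci_count == 0
    total_foci_area: int


@dataclass
class RunSummary:
    """What a batch run produced: records plus a manifest of files written."""

    records: list[NucleusRecord]
    manifest: list[Path] = field(default_factory=list)
    output_dir: Path = Path(".")
    n_images: int = 0

    @property
    def n_nuclei(self) -> int:
        return len(self.records)


def _relabel(labels: np.ndarray, kept: list[Region]) -> tuple[np.ndarray, list[Region]]:
    """Restrict a label map to the kept regions, renumbering them 1..k."""
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    new_regions = []
    for new_id, reg in enumerate(kept, start=1):
        lut[reg.label] = new_id
        new_regions.append(
            Region(label=new_id, area=reg.area, bbox=reg.bbox, centroid=reg.centroid)
        )
    return lut[labels], new_regions


def _touches_border(reg: Region, shape: tuple[int, int]) -> bool:
    r0, c0, r1, c1 = reg.bbox
    return r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]


def _segment_marker(
    marker: GrayImage, params: AnalysisParams
) -> tuple[np.ndarray, list[Region], list[Region]]:
    """Threshold + label the marker channel; returns the gated label map,
    the gated regions, and all pre-gate regions (for the size histogram)."""
    _, mask = otsu_threshold(marker, params.intensity_cutoff)
    labels, all_regions = label_components(mask, params.connectivity)
    kept = filter_by_area(all_regions, params.marker_area_min, params.marker_area_max)
    if params.exclude_edge_nuclei:
        kept = [r for r in kept if not _touches_border(r, marker.pixels.shape)]
    nucleus_labels, nuclei = _relabel(labels, kept)
    return nucleus_labels, nuclei, all_regions


def detect_nuclei(
    marker: GrayImage, params: AnalysisParams
) -> tuple[np.ndarray, list[Region]]:
    """Detect nuclei in a marker image.

    Otsu thresholding above the background cut-off, connected-component
    labeling, then pixel-area gating (and optional edge exclusion).  The
    returned label map contains only the surviving nuclei, renumbered 1..k.
    """
    params.validate()
    labels, nuclei, _ = _segment_marker(marker, params)
    return labels, nuclei


def _detect_foci_full(
    damage: GrayImage, nucleus_labels: np.ndarray, params: AnalysisParams
) -> tuple[dict[int, list[Region]], np.ndarray]:
    """Per-nucleus foci plus a global focus label map for rendering.

    The adaptive mask is computed once over the whole damage image (so
    bounding-box borders cannot create block artifacts), then intersected
    with each nucleus's pixel set; components are labelled per nucleus and
    size-filtered.  Signal outside every nucleus is discarded.
    """
    if damage.pixels.shape != nucleus_labels.shape:
        raise InvalidInputError(
            f"damage image {damage.pixels.shape} and nucleus labels "
            f"{nucleus_labels.shape} differ in shape"
        )
    damage_mask = adaptive_gaussian_mask(damage, params.block_size, params.c_offset)
    foci: dict[int, list[Region]] = {}
    foci_labels = np.zeros_like(nucleus_labels, dtype=np.int32)
    next_id = 0
    n_nuclei = int(nucleus_labels.max())
    for nucleus_id in range(1, n_nuclei + 1):
        inside = nucleus_labels == nucleus_id
        rows = np.flatnonzero(inside.any(axis=1))
        cols = np.flatnonzero(inside.any(axis=0))
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        sub = inside[r0:r1, c0:c1] & damage_mask[r0:r1, c0:c1]
        sub_labels, sub_regions = label_components(sub, params.connectivity)
        kept = filter_by_area(sub_regions, params.foci_area_min, None)
        shifted = []
        for reg in kept:
            next_id += 1
            br0, bc0, br1, bc1 = reg.bbox
            shifted.append(
                Region(
                    label=next_id,
                    area=reg.area,
                    bbox=(br0 + r0, bc0 + c0, br1 + r0, bc1 + c0),
                    centroid=(reg.centroid[0] + r0, reg.centroid[1] + c0),
                )
            )
            foci_labels[r0:r1, c0:c1][sub_labels == reg.label] = next_id
        foci[nucleus_id] = shifted
    return foci, foci_labels


def detect_foci(
    damage: GrayImage, nucleus_labels: np.ndarray, params: AnalysisParams
) -> dict[int, list[Region]]:
    """Detect DNA-damage foci inside each retained nucleus.

    Returns a map from nucleus id to the list of focus regions contained in
    that nucleus; nuclei without foci map to an empty list.
    """
    params.validate()
    foci, _ = _detect_foci_full(damage, nucleus_labels, params)
    return foci


def _records_from_foci(
    image_name: str, nuclei: list[Region], foci: dict[int, list[Region]]
) -> list[NucleusRecord]:
    records = []
    for nuc in nuclei:
        member = foci.get(nuc.label, [])
        total = sum(f.area for f in member)
        count = len(member)
        records.append(
            NucleusRecord(
                image_name=image_name,
                nucleus_id=nuc.label,
                nucleus_area=nuc.area,
                foci_count=count,
                mean_foci_area=total / count if count else 0.0,
                total_foci_area=total,
            )
        )
    return records


def quantify_pair(
    pair: tuple[GrayImage, GrayImage], params: AnalysisParams
) -> list[NucleusRecord]:
    """Quantify one marker/damage image pair: one record per retained
    nucleus, zero-foci nuclei included."""
    params.validate()
    marker, damage = pair
    nucleus_labels, nuclei = detect_nuclei(marker, params)
    foci = detect_foci(damage, nucleus_labels, params)
    return _records_from_foci(marker.source_name, nuclei, foci)


def format_mean(value: float) -> str:
    """Format a mean area with 2 decimals, rounding half up."""
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _write_quantification(records: list[NucleusRecord], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(QUANTIFICATION_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.image_name,
                    rec.nucleus_id,
                    rec.nucleus_area,
                    rec.foci_count,
                    format_mean(rec.mean_foci_area),
                    rec.total_foci_area,
                ]
            )


def _write_given_parameters(
    params: AnalysisParams, batch: ChannelBatch, output_name: str, path: Path
) -> None:
    rows = [("parameter", "value")]
    for f in fields(params):
        rows.append((f.name, str(getattr(params, f.name))))
    rows += [
        ("marker_dir", str(batch.marker_dir)),
        ("damage_dir", str(batch.damage_dir)),
        ("output_name", output_name),
        ("tool_version", __version__),
        ("timestamp", datetime.datetime.now().isoformat(timespec="seconds")),
    ]
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


def _write_intensity_artifacts(hist, cutoff: int, out_dir: Path) -> list[Path]:
    csv_path = out_dir / "pixel_intensity.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intensity", "count"])
        for i, c in enumerate(hist.counts):
            writer.writerow([i, int(c)])
    suggestion = suggest_cutoff(hist)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(np.arange(256), hist.counts, width=1.0, color="steelblue")
    ax.axvline(suggestion, color="crimson", linestyle="--", label=f"suggested cut-off = {suggestion}")
    if cutoff != suggestion:
        ax.axvline(cutoff, color="darkorange", linestyle=":", label=f"used cut-off = {cutoff}")
    ax.set_xlabel("pixel intensity")
    ax.set_ylabel("pixel count (all images)")
    ax.set_title("pixel_intensity")
    ax.legend()
    png_path = out_dir / "pixel_intensity.png"
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return [csv_path, png_path]


def _write_marker_size_artifacts(
    regions_per_image: list[list[Region]], out_dir: Path, bin_width: int = 100
) -> list[Path]:
    edges, counts = marker_size_histogram(regions_per_image, bin_width=bin_width)
    csv_path = out_dir / "MARKER_size.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_low", "bin_high", "count"])
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            writer.writerow([int(lo), int(hi), int(c)])
    fig, ax = plt.subplots(figsize=(7, 4))
    if counts.size:
        ax.bar(edges[:-1], counts, width=bin_width, align="edge", color="seagreen")
    ax.set_xlabel("object area (px)")
    ax.set_ylabel("object count")
    ax.set_title("MARKER_size")
    png_path = out_dir / "MARKER_size.png"
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return [csv_path, png_path]


def prepare_output_dir(output_name: str, root: str | Path = ".") -> Path:
    """Create the run's output folder, refusing the reserved name and any
    pre-existing folder (existing results stay intact)."""
    if not output_name:
        raise InvalidOutputError("output name must be non-empty")
    if output_name == RESERVED_OUTPUT_NAME:
        raise InvalidOutputError(
            f"output name {RESERVED_OUTPUT_NAME!r} is reserved by the application"
        )
    out_dir = Path(root) / output_name
    if out_dir.exists():
        raise InvalidOutputError(
            f"output folder {out_dir} already exists; choose a new name"
        )
    out_dir.mkdir(parents=True)
    return out_dir


def run_batch(
    batch: ChannelBatch,
    params: AnalysisParams,
    output_name: str,
    root: str | Path = ".",
) -> RunSummary:
    """Process every image pair of a batch and write the full output tree.

    Pairs are processed independently; a degenerate image yields zero
    nuclei (with a logged warning) and the run continues.  Returns a
    :class:`RunSummary` whose record list matches Quantification.csv
    row-for-row.
    """
    params.validate()
    out_dir = prepare_output_dir(output_name, root)
    dirs = {
        name: out_dir / name
        for name in (
            "Output_images_nucleus",
            "Output_images_DNAdamage",
            "Output_images_overlaid",
        )
    }
    for d in dirs.values():
        d.mkdir()

    manifest: list[Path] = []
    records: list[NucleusRecord] = []
    all_marker_regions: list[list[Region]] = []
    for marker, damage in batch.pairs:
        nucleus_labels, nuclei, pre_gate = _segment_marker(marker, params)
        foci, foci_labels = _detect_foci_full(damage, nucleus_labels, params)
        pair_records = _records_from_foci(marker.source_name, nuclei, foci)
        records.extend(pair_records)
        all_marker_regions.append(pre_gate)
        logger.info(
            "%s: %d nuclei, %d foci",
            marker.source_name,
            len(nuclei),
            sum(len(v) for v in foci.values()),
        )
        stem = Path(marker.source_name).stem or "image"
        nucleus_png = dirs["Output_images_nucleus"] / f"{stem}.png"
        damage_png = dirs["Output_images_DNAdamage"] / f"{stem}.png"
        overlay_png = dirs["Output_images_overlaid"] / f"{stem}.png"
        write_label_image(nucleus_labels, nucleus_png)
        write_label_image(foci_labels, damage_png)
        write_overlay(damage, foci_labels, overlay_png)
        manifest += [nucleus_png, damage_png, overlay_png]

    quant_path = out_dir / "Quantification.csv"
    _write_quantification(records, quant_path)
    params_path = out_dir / "Given_parameters.csv"
    _write_given_parameters(params, batch, output_name, params_path)
    hist = batch_intensity_histogram([m for m, _ in batch.pairs])
    manifest += _write_intensity_artifacts(hist, params.intensity_cutoff, out_dir)
    manifest += _write_marker_size_artifacts(all_marker_regions, out_dir)
    manifest += [quant_path, params_path]
    return RunSummary(
        records=records,
        manifest=manifest,
        output_dir=out_dir,
        n_images=len(batch),
    )
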