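"""Per-sample runs, batch processing and CSV export.

One *sample* is either a brightfield/fluorescent image pair (fluorescence
mode) or a single white-background RGB image (colorimetric mode).  Each run
produces a :class:`SampleRecord` — counts, chi-squared verdict, the
parameters actually used and any warnings — and a batch writes one CSV row
per record.  Failures inside a batch are logged and isolated; the remaining
samples still run.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

from . import imaging
from .colorimetric import ColorClassParams, classify_colorimetric
from .errors import BatchError, ConstantImageError, ParameterError, SeedScreenError
from .overlay import render_overlay
from .segmentation import SegmentationParams, resolve_intensity_threshold, segment_seeds
from .segregation import SeedCounts, chi_squared_segregation, combine_counts

log = logging.getLogger(__name__)

#: Fixed CSV schema (RFC-4180, UTF-8, header row).  ``warnings`` holds a
#: ``|``-separated list; empty statistics (no seeds) serialise as "".
CSV_COLUMNS = [
    "sample_id", "mode", "n_total", "n_transgenic", "n_wildtype",
    "chi2", "p_value", "call",
    "bf_intensity", "fl_intensity", "radial_threshold", "radial_ratio",
    "warnings",
]

ADJUSTED_FLAG = "manually_adjusted"


@dataclass(frozen=True)
class SampleRecord:
    """Result row for one sample."""

    sample_id: str
    mode: str  # "fluorescence" | "colorimetric"
    n_total: int
    n_transgenic: int
    n_wildtype: int
    chi2: float | None
    p_value: float | None
    call: str
    bf_intensity: float | None
    fl_intensity: float | None
    radial_threshold: float | None
    radial_ratio: float | None
    warnings: tuple[str, ...] = ()

    @property
    def manually_adjusted(self) -> bool:
        return ADJUSTED_FLAG in self.warnings


def _stats_fields(counts: SeedCounts, alpha: float):
    if counts.n_total == 0:
        return None, None, "", ("no seeds detected; statistics skipped",)
    res = chi_squared_segregation(counts, alpha=alpha)
    return res.chi2_statistic, res.p_value, res.call, ()


def run_fluorescence(
    brightfield_path,
    fluorescent_path,
    params: SegmentationParams | None = None,
    fl_params: SegmentationParams | None = None,
    *,
    alpha: float = 0.05,
    sample_id: str | None = None,
    overlay_dir=None,
) -> SampleRecord:
    """Analyse one brightfield/fluorescent pair.

    The brightfield frame (inverted so seeds are bright) yields the total
    count; the fluorescent frame the transgenic count.  Separate
    segmentation parameters may be given per channel because the two
    channels usually need different intensity thresholds.
    """
    t0 = time.perf_counter()
    params = params or SegmentationParams()
    fl_params = fl_params or params
    sid = sample_id or Path(brightfield_path).stem.removesuffix("_BF")

    bf = imaging.to_grayscale(imaging.load_image(brightfield_path))
    fl = imaging.to_grayscale(imaging.load_image(fluorescent_path))
    if bf.shape != fl.shape:
        raise ParameterError(
            f"{sid}: image dimensions differ ({bf.shape} vs {fl.shape})"
        )
    bf = imaging.remove_scale_bar(imaging.invert(bf))
    fl = imaging.remove_scale_bar(fl)

    try:
        params = resolve_intensity_threshold(bf, params)
        fl_params = resolve_intensity_threshold(fl, fl_params)
    except ConstantImageError:
        pass  # blank frame: segment_seeds will report 0 seeds
    bf_labels, bf_regions = segment_seeds(bf, params)
    fl_labels, fl_regions = segment_seeds(fl, fl_params)

    counts = combine_counts(len(bf_regions), len(fl_regions))
    chi2, p, call, warn = _stats_fields(counts, alpha)

    if overlay_dir is not None:
        d = Path(overlay_dir)
        d.mkdir(parents=True, exist_ok=True)
        render_overlay(bf, bf_labels, path=d / f"{sid}_BF_overlay.png")
        render_overlay(fl, fl_labels, path=d / f"{sid}_FL_overlay.png")

    log.info("%s: fluorescence run in %.2fs (total=%d marker=%d)",
             sid, time.perf_counter() - t0, counts.n_total, counts.n_transgenic)
    return SampleRecord(
        sample_id=sid, mode="fluorescence",
        n_total=counts.n_total, n_transgenic=counts.n_transgenic,
        n_wildtype=counts.n_wildtype,
        chi2=chi2, p_value=p, call=call,
        bf_intensity=(None if params.intensity_threshold == "auto"
                      else float(params.intensity_threshold)),
        fl_intensity=(None if fl_params.intensity_threshold == "auto"
                      else float(fl_params.intensity_threshold)),
        radial_threshold=params.radial_threshold,
        radial_ratio=(params.radial_threshold_ratio
                      if params.radial_threshold is None else None),
        warnings=warn,
    )


def run_colorimetric(
    rgb_path,
    params: ColorClassParams | None = None,
    *,
    alpha: float = 0.05,
    sample_id: str | None = None,
    overlay_dir=None,
) -> SampleRecord:
    """Analyse one colorimetric (RUBY) RGB image."""
    t0 = time.perf_counter()
    params = params or ColorClassParams()
    sid = sample_id or Path(rgb_path).stem.removesuffix("_RGB")
    rgb = imaging.load_image(rgb_path)

    result = classify_colorimetric(rgb, params)
    n_all, n_ruby = result.counts
    counts = combine_counts(n_all, n_ruby)
    chi2, p, call, warn = _stats_fields(counts, alpha)

    if overlay_dir is not None:
        d = Path(overlay_dir)
        d.mkdir(parents=True, exist_ok=True)
        ruby_ids = {r.label for r in result.ruby_regions}
        classes = {r.label: ("ruby" if r.label in ruby_ids else "wildtype")
                   for r in result.all_regions}
        render_overlay(rgb, result.labels, classes=classes,
                       path=d / f"{sid}_RGB_overlay.png")

    seg = params.segmentation
    log.info("%s: colorimetric run in %.2fs (total=%d ruby=%d)",
             sid, time.perf_counter() - t0, n_all, n_ruby)
    return SampleRecord(
        sample_id=sid, mode="colorimetric",
        n_total=counts.n_total, n_transgenic=counts.n_transgenic,
        n_wildtype=counts.n_wildtype,
        chi2=chi2, p_value=p, call=call,
        bf_intensity=result.L_threshold, fl_intensity=None,
        radial_threshold=seg.radial_threshold,
        radial_ratio=(seg.radial_threshold_ratio
                      if seg.radial_threshold is None else None),
        warnings=warn,
    )


def adjust_counts(
    record: SampleRecord,
    corrected_total: int | None = None,
    corrected_transgenic: int | None = None,
    *,
    alpha: float = 0.05,
) -> SampleRecord:
    """Manual count override: replace counts, recompute the chi-squared test.

    The returned record carries a ``manually_adjusted`` flag in its warnings.
    With no corrections the record is returned unchanged (and unflagged).
    """
    if corrected_total is None and corrected_transgenic is None:
        return record
    total = record.n_total if corrected_total is None else int(corrected_total)
    trans = record.n_transgenic if corrected_transgenic is None else int(corrected_transgenic)
    counts = combine_counts(total, trans)  # validates trans <= total, >= 0
    chi2, p, call, warn = _stats_fields(counts, alpha)
    return replace(
        record,
        n_total=counts.n_total, n_transgenic=counts.n_transgenic,
        n_wildtype=counts.n_wildtype, chi2=chi2, p_value=p, call=call,
        warnings=tuple(w for w in record.warnings if w != ADJUSTED_FLAG)
        + warn + (ADJUSTED_FLAG,),
    )


# ---------------------------------------------------------------------------
# batch discovery and CSV round-trip

def _discover_directory(directory: Path):
    samples = []
    for bf in sorted(directory.glob("*_BF.*")):
        sid = bf.name.rsplit("_BF.", 1)[0]
        fls = sorted(directory.glob(f"{sid}_FL.*"))
        if fls:
            samples.append({"sample_id": sid, "mode": "fluorescence",
                            "brightfield": str(bf), "fluorescent": str(fls[0])})
    for rgb in sorted(directory.glob("*_RGB.*")):
        if "_overlay" in rgb.name:
            continue
        sid = rgb.name.rsplit("_RGB.", 1)[0]
        samples.append({"sample_id": sid, "mode": "colorimetric", "rgb": str(rgb)})
    return samples


def _read_manifest(path: Path):
    base = path.parent
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entry = {"sample_id": row["sample_id"],
                     "mode": row.get("mode", "fluorescence") or "fluorescence"}
            for key in ("brightfield", "fluorescent", "rgb"):
                if row.get(key):
                    p = Path(row[key])
                    entry[key] = str(p if p.is_absolute() else base / p)
            samples.append(entry)
    return samples


def run_batch(
    source,
    out_csv=None,
    *,
    params: SegmentationParams | None = None,
    fl_params: SegmentationParams | None = None,
    color_params: ColorClassParams | None = None,
    alpha: float = 0.05,
    overlay_dir=None,
):
    """Process every sample from a directory or manifest CSV.

    A directory is scanned for ``<id>_BF.*``/``<id>_FL.*`` pairs and
    ``<id>_RGB.*`` images; a manifest CSV (columns ``sample_id, mode,
    brightfield, fluorescent, rgb``; relative paths resolved against the
    manifest) overrides the naming convention.  Per-sample failures are
    logged and collected, never abort the batch.  Returns
    ``(records, failures)`` where ``failures`` is a list of
    ``(sample_id, message)``; the CSV (one row per successful record) is
    written when ``out_csv`` is given.
    """
    source = Path(source)
    if source.is_dir():
        samples = _discover_directory(source)
    elif source.is_file():
        samples = _read_manifest(source)
    else:
        raise BatchError(f"batch source {source} is neither a directory nor a file")
    if not samples:
        raise BatchError(f"no samples found in {source}")

    records, failures = [], []
    for s in samples:
        sid = s["sample_id"]
        try:
            if s["mode"] == "colorimetric":
                rec = run_colorimetric(
                    s["rgb"], color_params, alpha=alpha,
                    sample_id=sid, overlay_dir=overlay_dir,
                )
            else:
                rec = run_fluorescence(
                    s["brightfield"], s["fluorescent"], params, fl_params,
                    alpha=alpha, sample_id=sid, overlay_dir=overlay_dir,
                )
            records.append(rec)
        except (SeedScreenError, OSError, KeyError) as exc:
            log.error("%s: failed (%s)", sid, exc)
            failures.append((sid, str(exc)))
    log.info("batch: %d lines tested, %d failed (alpha=%.3g, no multiple-testing "
             "correction applied)", len(records), len(failures), alpha)
    if out_csv is not None:
        write_records_csv(records, out_csv)
    return records, failures


def _fmt(v):
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def write_records_csv(records, path) -> None:
    """One RFC-4180 row per record; floats via ``repr`` so parsing them back
    reproduces every field exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id, r.mode, r.n_total, r.n_transgenic, r.n_wildtype,
                _fmt(r.chi2), _fmt(r.p_value), r.call,
                _fmt(r.bf_intensity), _fmt(r.fl_intensity),
                _fmt(r.radial_threshold), _fmt(r.radial_ratio),
                "|".join(r.warnings),
            ])


def read_records_csv(path) -> list[SampleRecord]:
    """Inverse of :func:`write_records_csv`."""
    def _f(s):
        return None if s == "" else float(s)

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(SampleRecord(
                sample_id=row["sample_id"], mode=row["mode"],
                n_total=int(row["n_total"]),
                n_transgenic=int(row["n_transgenic"]),
                n_wildtype=int(row["n_wildtype"]),
                chi2=_f(row["chi2"]), p_value=_f(row["p_value"]),
                call=row["call"],
                bf_intensity=_f(row["bf_intensity"]),
                fl_intensity=_f(row["fl_intensity"]),
                radial_threshold=_f(row["radial_threshold"]),
                radial_ratio=_f(row["radial_ratio"]),
                warnings=tuple(w for w in row["warnings"].split("|") if w),
            ))
    return out
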