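"""Probe-table input, SEG-style output, and lookup-model serialization.

Probe input is tab-delimited with a header naming at least
(sample, chrom, position, log2ratio); an optional ``snr`` column enables
signal-to-noise filtering (probes with SNR below threshold are dropped, the
default threshold 1.0 matching common aCGH preprocessing).  Rows with a
missing position or non-finite ratio are dropped, never imputed.  Segment
output is a SEG-style TSV ordered by sample, then natural chromosome order
(1..22, X, Y, then lexicographic), then start.  The lookup model
serializes to a single versioned JSON document: portable, diffable, and
bit-exact on round trip (JSON decimal strings reproduce IEEE doubles).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .maxt import ProbeSeries
from .segmentation import SegmentRecord
from .xmodel import MODEL_FORMAT_VERSION, XtremeModel

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ("sample", "chrom", "position", "log2ratio")
SEG_COLUMNS = (
    "sample", "chrom", "start_pos", "end_pos", "n_probes", "seg_mean", "p_value"
)


class ProbeTableFormatError(ValueError):
    pass


class ModelFormatError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Probe filters: SNR threshold applied when an snr column is present."""

    snr_min: float = 1.0
    snr_filter: bool = True


def chrom_sort_key(chrom: str):
    """Natural chromosome order: 1..22, X, Y, then anything else."""
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    if c.isdigit():
        return (0, int(c), "")
    if c.upper() in ("X", "Y"):
        return (1, 0 if c.upper() == "X" else 1, "")
    return (2, 0, c)


def read_probe_table(
    path: str | Path, filters: FilterSpec | None = None
) -> list[ProbeSeries]:
    """Read a probe-level TSV into per-(sample, chromosome) series.

    Probes are sorted by genomic position within each chromosome; dropped
    rows (missing position, non-finite ratio, low SNR) are logged.  Probes
    sharing a position are kept as-is and flagged in the log.
    """
    filters = filters or FilterSpec()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    except Exception as exc:
        raise ProbeTableFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ProbeTableFormatError(
            f"{path}: header must name columns {PROBE_COLUMNS}, missing {missing}"
        )
    n_in = len(df)
    pos = pd.to_numeric(df["position"], errors="coerce")
    ratio = pd.to_numeric(df["log2ratio"], errors="coerce")
    keep = pos.notna() & np.isfinite(ratio.fillna(np.inf))
    if "snr" in df.columns and filters.snr_filter:
        snr = pd.to_numeric(df["snr"], errors="coerce")
        keep &= snr.notna() & (snr >= filters.snr_min)
    dropped = n_in - int(keep.sum())
    if dropped:
        logger.info("%s: dropped %d of %d probe rows", path.name, dropped, n_in)
    df = df.loc[keep].assign(position=pos[keep].astype(np.int64),
                             log2ratio=ratio[keep].astype(float))
    out: list[ProbeSeries] = []
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("position", kind="mergesort")
        if grp.empty:
            logger.warning("%s/%s empty after filtering; skipped", sample, chrom)
            continue
        if grp["position"].duplicated().any():
            logger.warning(
                "%s/%s: duplicate probe positions kept as-is", sample, chrom
            )
        out.append(
            ProbeSeries(
                values=grp["log2ratio"].to_numpy(),
                sample_id=str(sample),
                chrom=str(chrom),
                positions=grp["position"].to_numpy(),
            )
        )
    out.sort(key=lambda s: (s.sample_id, chrom_sort_key(s.chrom)))
    return out


def write_segments(segments: list[SegmentRecord], path: str | Path) -> None:
    """Write SEG-style TSV; absent p-values are emitted as NA."""
    _check_tiling(segments)
    rows = sorted(
        segments,
        key=lambda r: (r.sample_id, chrom_sort_key(r.chrom), r.start_index),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for r in rows:
            p = "NA" if r.p_value is None else format(r.p_value, ".6g")
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start_pos}\t{r.end_pos}\t"
                f"{r.n_probes}\t{r.seg_mean:.6g}\t{p}\n"
            )


def _check_tiling(segments: list[SegmentRecord]) -> None:
    by_chrom: dict[tuple[str, str], list[SegmentRecord]] = {}
    for r in segments:
        by_chrom.setdefault((r.sample_id, r.chrom), []).append(r)
    for key, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.start_index)
        expect = 1
        for r in recs:
            if r.start_index != expect or r.end_index < r.start_index:
                raise ValueError(
                    f"segments of {key} do not tile: gap/overlap at index "
                    f"{r.start_index} (expected {expect})"
                )
            if r.n_probes != r.end_index - r.start_index + 1:
                raise ValueError(f"inconsistent n_probes in {key}")
            expect = r.end_index + 1


def save_model(model: XtremeModel, path: str | Path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_axis": model.n_axis.tolist(),
        "sk_axis": model.sk_axis.tolist(),
        "ku_axis": model.ku_axis.tolist(),
        "gamma_table": model.gamma_table.tolist(),
        "sigma_table": model.sigma_table.tolist(),
        "mu_table": model.mu_table.tolist(),
        "replicates_per_cell": model.replicates_per_cell,
        "build_seed": model.build_seed,
        "scan_min_width": model.scan_min_width,
        "flagged_cells": model.flagged_cells,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path) -> XtremeModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version!r}, expected "
            f"{MODEL_FORMAT_VERSION}"
        )
    required = (
        "n_axis", "sk_axis", "ku_axis",
        "gamma_table", "sigma_table", "mu_table",
        "replicates_per_cell", "build_seed",
    )
    for key in required:
        if key not in doc:
            raise ModelFormatError(f"{path}: missing component {key!r}")
    return XtremeModel(
        n_axis=np.asarray(doc["n_axis"], dtype=float),
        sk_axis=np.asarray(doc["sk_axis"], dtype=float),
        ku_axis=np.asarray(doc["ku_axis"], dtype=float),
        gamma_table=np.asarray(doc["gamma_table"], dtype=float),
        sigma_table=np.asarray(doc["sigma_table"], dtype=float),
        mu_table=np.asarray(doc["mu_table"], dtype=float),
        replicates_per_cell=int(doc["replicates_per_cell"]),
        build_seed=int(doc["build_seed"]),
        scan_min_width=int(doc.get("scan_min_width", 2)),
        flagged_cells=list(doc.get("flagged_cells", [])),
    )


def setup_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
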