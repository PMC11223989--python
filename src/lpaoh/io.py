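"""Readers and writers for the package's plain-text interchange formats.

Coordinates are 1-based in panel/counts inputs (VCF convention) and 0-based
half-open in BED/bedGraph outputs. Panel files are either a sites VCF
(biallelic SNVs; alternate-allele frequency from a configurable INFO key,
default ``AF``) or a headerless 5-column TSV chrom, pos, ref, alt, af.
Counts are a 4-column TSV chrom, pos, ref_count, alt_count. Lines starting
with ``#`` are comments everywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .smoothing import AOHSegment, segments_to_frame
from .simulate import TruthSegment

__all__ = [
    "read_panel",
    "write_panel_tsv",
    "write_panel_vcf",
    "read_counts",
    "write_counts",
    "write_segments_bed",
    "read_segments_bed",
    "write_bedgraph",
    "write_truth_bed",
    "read_truth_bed",
    "read_yaml",
    "write_yaml",
    "write_json",
]

logger = logging.getLogger(__name__)

_PANEL_COLS = ["chrom", "pos", "ref", "alt", "af"]
_COUNT_COLS = ["chrom", "pos", "ref_count", "alt_count"]


def _read_tsv(path, names, dtypes) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=names, dtype=dtypes
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"malformed TSV {path}: {exc}") from exc
    return df


def read_panel(path: str | Path, af_key: str = "AF") -> pd.DataFrame:
    """Read an allele-frequency panel from a sites VCF or a 5-column TSV.

    Multi-allelic and non-SNV VCF rows are dropped with a logged count.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_panel_vcf(path, af_key)
    df = _read_tsv(
        path,
        _PANEL_COLS,
        {"chrom": str, "pos": np.int64, "ref": str, "alt": str, "af": np.float64},
    )
    if df["af"].isna().any() or (df["af"] < 0).any() or (df["af"] > 1).any():
        raise InputError(f"panel {path} has allele frequencies outside [0, 1]")
    return df


def _read_panel_vcf(path: Path, af_key: str) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    dropped = 0
    for variant in VCF(str(path)):
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            dropped += 1
            continue
        af = variant.INFO.get(af_key)
        if af is None:
            dropped += 1
            continue
        if isinstance(af, (tuple, list)):
            af = af[0]
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0], float(af)))
    if dropped:
        logger.warning("%d multi-allelic/non-SNV/AF-less VCF rows dropped", dropped)
    if not rows:
        raise InputError(f"no usable biallelic SNV rows in {path}")
    return pd.DataFrame(rows, columns=_PANEL_COLS)


def write_panel_tsv(panel: pd.DataFrame, path: str | Path) -> None:
    panel[_PANEL_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_panel_vcf(
    panel: pd.DataFrame,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
    af_key: str = "AF",
) -> None:
    """Write the panel as an uncompressed sites VCF (no genotypes)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta(
        "INFO",
        items=[
            ("ID", af_key),
            ("Number", "A"),
            ("Type", "Float"),
            ("Description", "Alternate allele frequency"),
        ],
    )
    lengths = dict(chrom_lengths or {})
    for chrom in dict.fromkeys(panel["chrom"]):
        length = int(lengths.get(chrom, int(panel.loc[panel["chrom"] == chrom, "pos"].max()) + 1))
        header.contigs.add(str(chrom), length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in panel.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info[af_key] = float(row.af)
            vcf.write(rec)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        _COUNT_COLS,
        {"chrom": str, "pos": np.int64, "ref_count": np.int64, "alt_count": np.int64},
    )
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise InputError(f"negative read counts in {path}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[_COUNT_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_segments_bed(segments: Sequence[AOHSegment], path: str | Path) -> None:
    """BED4+: chrom, start, end, name, mean_posterior, size_class, flag."""
    frame = segments_to_frame(segments)
    with open(path, "w") as fh:
        for i, row in frame.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tAOH_{i + 1}\t"
                f"{row.mean_posterior:.4f}\t{row.size_class}\t{row.flag}\n"
            )


def read_segments_bed(path: str | Path) -> list[AOHSegment]:
    segments = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: malformed BED row") from exc
            posterior = float(parts[4]) if len(parts) > 4 and parts[4] else 1.0
            size_class = parts[5] if len(parts) > 5 and parts[5] else "gt10"
            flag = parts[6] if len(parts) > 6 else ""
            segments.append(
                AOHSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    mean_posterior=posterior,
                    n_bins=1,
                    size_class=size_class,
                    flag=flag,
                )
            )
    return segments


def write_bedgraph(
    bins: pd.DataFrame, value_col: str, path: str | Path, precision: int = 6
) -> None:
    with open(path, "w") as fh:
        for row in bins.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{getattr(row, value_col):.{precision}f}\n"
            )


def write_truth_bed(truth: Sequence[TruthSegment], path: str | Path) -> None:
    """BED with mosaic fraction and copy state in columns 5-6."""
    with open(path, "w") as fh:
        for i, seg in enumerate(truth, 1):
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\ttruth_{i}\t"
                f"{seg.mosaic_f:.4f}\t{seg.cn_state}\n"
            )


def read_truth_bed(path: str | Path) -> list[TruthSegment]:
    truth = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                mosaic_f = float(parts[4]) if len(parts) > 4 else 1.0
                cn_state = parts[5] if len(parts) > 5 else "neutral"
                truth.append(
                    TruthSegment(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        mosaic_f=mosaic_f,
                        cn_state=cn_state,
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: malformed truth BED row") from exc
    return truth


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError(f"{path}: expected a YAML mapping")
    return data


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


def write_json(data: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(dict(data), fh, indent=2, default=_default)
        fh.write("\n")
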