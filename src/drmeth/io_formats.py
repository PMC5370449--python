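"""Readers/writers for the external text formats and the core CpG container.

The central in-memory object is :class:`CpGTable`: per-CpG methylated and
unmethylated read counts for a set of samples, each sample assigned to one of
the four study groups (diet x age).  Counts are primary data; the percentage
column of bismark-style coverage files is derived and only sanity-checked on
input.

Coordinate conventions: coverage files are 1-based inclusive (bismark
dialect), BED files and all internal interval frames are 0-based half-open.
CpG positions are stored 1-based (position of the cytosine), strand-combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import BED_COLUMNS, as_intervals

log = logging.getLogger("drmeth")

#: the four study groups: diet (AL ad libitum / DR dietary restriction) x age
GROUPS = ("AL_young", "AL_old", "DR_young", "DR_old")

COVERAGE_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CpGTable:
    """Per-CpG (meth, unmeth) counts for every sample.

    ``df`` is indexed by (chrom, pos) with pos the 1-based cytosine
    coordinate, strictly increasing within each chromosome.  Columns are a
    MultiIndex (sample, field) with field in {"meth", "unmeth"}.  Missing
    coverage is represented as (0, 0).
    """

    df: pd.DataFrame
    sample_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for s, g in self.sample_groups.items():
            if g not in GROUPS:
                raise DataError(f"sample {s!r} mapped to unknown group {g!r}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values(0)))

    @property
    def n_cpgs(self) -> int:
        return len(self.df)

    def counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.df[(sample, "meth")].to_numpy(),
            self.df[(sample, "unmeth")].to_numpy(),
        )

    def subset_rows(self, mask: np.ndarray) -> "CpGTable":
        return CpGTable(self.df.loc[mask], dict(self.sample_groups))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.df, index=True).to_numpy().tobytes())
        return h.hexdigest()


def _build_table(frames: dict[str, pd.DataFrame], sample_groups: Mapping[str, str]) -> CpGTable:
    pieces = []
    for sample, sub in frames.items():
        sub = sub.set_index(["chrom", "pos"])
        sub.columns = pd.MultiIndex.from_product([[sample], ["meth", "unmeth"]])
        pieces.append(sub)
    df = pd.concat(pieces, axis=1, join="outer")
    df = df.fillna(0).astype(np.int64)
    df = df.sort_index()
    return CpGTable(df, dict(sample_groups))


def read_coverage(
    paths: Sequence[str | Path],
    sample_groups: Mapping[str, str],
    sample_names: Sequence[str] | None = None,
    pct_tolerance: float = 0.5,
) -> CpGTable:
    """Read bismark-style coverage files (one per sample) into a CpGTable.

    Each file has six tab-separated columns: chrom, start, end (1-based,
    inclusive, start == end == cytosine position), methylation percentage,
    methylated count, unmethylated count.  Counts win over the percentage
    column; an inconsistency beyond ``pct_tolerance`` points is logged.
    """
    paths = [Path(p) for p in paths]
    if sample_names is None:
        sample_names = [p.name.split(".")[0] for p in paths]
    if len(set(sample_names)) != len(sample_names):
        raise DataError("duplicate sample names")
    frames = {}
    for path, sample in zip(paths, sample_names):
        try:
            raw = pd.read_csv(
                path, sep="\t", names=COVERAGE_COLUMNS, header=None,
                dtype={"chrom": str, "start": np.int64, "end": np.int64,
                       "pct": float, "meth": np.int64, "unmeth": np.int64},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise DataError(f"{path}: malformed coverage file: {exc}") from exc
        if (raw["meth"] < 0).any() or (raw["unmeth"] < 0).any():
            raise DataError(f"{path}: negative counts")
        dup = raw.duplicated(subset=["chrom", "start"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise DataError(f"{path}: duplicate position at line {i + 1}")
        cov = raw["meth"] + raw["unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            expect = 100.0 * raw["meth"] / cov
        bad = cov.gt(0) & (expect - raw["pct"]).abs().gt(pct_tolerance)
        if bad.any():
            log.warning(
                "%s: %d lines with %% column inconsistent with counts "
                "(> %.2f points); counts used", path, int(bad.sum()), pct_tolerance,
            )
        frames[sample] = pd.DataFrame(
            {"chrom": raw["chrom"], "pos": raw["start"],
             "meth": raw["meth"], "unmeth": raw["unmeth"]}
        )
        if sample not in sample_groups:
            raise DataError(f"sample {sample!r} missing from sample_groups")
    return _build_table(frames, {s: sample_groups[s] for s in sample_names})


def write_coverage(table: CpGTable, outdir: str | Path) -> list[Path]:
    """Write one bismark-style coverage file per sample (1-based inclusive)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    chrom = table.df.index.get_level_values(0)
    pos = table.df.index.get_level_values(1)
    for sample in table.samples:
        meth, unmeth = table.counts(sample)
        cov = meth + unmeth
        keep = cov > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(keep, 100.0 * meth / np.where(cov > 0, cov, 1), 0.0)
        out = pd.DataFrame(
            {"chrom": chrom[keep], "start": pos[keep], "end": pos[keep],
             "pct": np.round(pct[keep], 6), "meth": meth[keep], "unmeth": unmeth[keep]}
        )
        path = outdir / f"{sample}.cov"
        out.to_csv(path, sep="\t", header=False, index=False)
        written.append(path)
    return written


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/6/12 into an interval frame (0-based half-open).

    For BED12 gene models the full chromStart..chromEnd span is used as the
    gene body; thick coordinates and block structure are ignored.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = raw.shape[1]
    if ncol < 3:
        raise DataError(f"{path}: BED needs >=3 columns")
    df = raw.iloc[:, : min(ncol, 6)].copy()
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    try:
        return as_intervals(df[BED_COLUMNS])
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    df = as_intervals(df)
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def merge_replicates(table: CpGTable) -> CpGTable:
    """Sum counts of replicate samples per group ("data group" merging).

    Returns a CpGTable whose samples are the group names themselves.
    """
    by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sample in table.samples:
        g = table.sample_groups.get(sample)
        if g is None:
            raise DataError(f"sample {sample!r} has no group assignment")
        by_group[g].append(sample)
    present = {g: ss for g, ss in by_group.items() if ss}
    if not present:
        raise DataError("no samples to merge")
    empty = [g for g, ss in by_group.items() if not ss]
    if empty:
        raise DataError(f"empty groups: {empty}")
    cols = {}
    for g, ss in present.items():
        cols[(g, "meth")] = sum(table.df[(s, "meth")] for s in ss)
        cols[(g, "unmeth")] = sum(table.df[(s, "unmeth")] for s in ss)
    df = pd.DataFrame(cols, index=table.df.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return CpGTable(df, {g: g for g in present})


def group_levels(table: CpGTable) -> pd.DataFrame:
    """Per-CpG methylation percentage per sample/group (NaN if uncovered)."""
    out = {}
    for s in table.samples:
        m, u = table.counts(s)
        cov = m + u
        with np.errstate(invalid="ignore", divide="ignore"):
            out[s] = np.where(cov > 0, 100.0 * m / np.where(cov > 0, cov, 1), np.nan)
    return pd.DataFrame(out, index=table.df.index)
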