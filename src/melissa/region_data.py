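"""Reading, binarising and regionalising single-cell CpG methylation calls.

Single-cell bisulfite sequencing yields, per cell, a sparse table of CpG
coordinates with methylated / total read counts.  Because each site in a
single cell is (almost always) either methylated on both alleles or on
neither, calls are binarised from the methylation ratio; hemi-methylated
sites (ratio exactly 0.5) are ambiguous and dropped.  CpGs are then mapped
into annotated genomic regions (e.g. promoter windows around a TSS) with
coordinates affinely scaled to [-1, 1], the canonical domain of the basis
functions used by the profile models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionAnnotation",
    "RegionCellData",
    "MethylomeDataset",
    "read_cell_calls",
    "read_annotations",
    "build_regions",
    "filter_regions",
    "split_train_test",
    "write_dataset",
    "read_dataset",
]


class EmptyDatasetError(ValueError):
    """Raised when filtering removes every region."""


@dataclass(frozen=True)
class RegionAnnotation:
    """A genomic region with an anchor point for relative positioning.

    ``start``/``end`` are 1-based inclusive genomic coordinates; the anchor
    (e.g. a TSS) must lie inside the interval and maps to relative
    coordinate 0.  Minus-strand regions are read 5'->3', i.e. relative
    positions are negated.
    """

    region_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"region {self.region_id}: strand must be +, - or .")
        if self.anchor is None:
            object.__setattr__(self, "anchor", (self.start + self.end) // 2)
        if not (self.start <= self.anchor <= self.end):
            raise ValueError(f"region {self.region_id}: anchor outside [start, end]")

    @property
    def half_width(self) -> float:
        return max(self.anchor - self.start, self.end - self.anchor)

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "chromosome": self.chromosome,
            "start": int(self.start),
            "end": int(self.end),
            "strand": self.strand,
            "anchor": int(self.anchor),
        }


@dataclass
class RegionCellData:
    """Observed CpGs of one cell in one region: scaled positions + states."""

    positions: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.positions.shape != self.states.shape or self.positions.ndim != 1:
            raise ValueError("positions and states must be equal-length vectors")
        if self.positions.size:
            if not np.all(np.diff(self.positions) > 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions.min() < -1 - 1e-9 or self.positions.max() > 1 + 1e-9:
                raise ValueError("positions must lie in [-1, 1]")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")

    def __len__(self) -> int:
        return int(self.positions.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionCellData):
            return NotImplemented
        return (
            self.positions.shape == other.positions.shape
            and np.allclose(self.positions, other.positions)
            and np.array_equal(self.states, other.states)
        )


class MethylomeDataset:
    """Ragged N-cells x M-regions collection of per-region CpG observations.

    ``data`` maps ``(cell_id, region_id)`` to :class:`RegionCellData`; a
    missing key means the region is uncovered in that cell.
    """

    def __init__(
        self,
        cells: list[str],
        regions: list[RegionAnnotation],
        data: Mapping[tuple[str, str], RegionCellData],
    ) -> None:
        if not cells or not regions:
            raise ValueError("dataset needs at least one cell and one region")
        self.cells = list(cells)
        self.regions = list(regions)
        self.data = dict(data)
        region_ids = {r.region_id for r in self.regions}
        cell_ids = set(self.cells)
        for cell, region in self.data:
            if cell not in cell_ids or region not in region_ids:
                raise ValueError(f"data key ({cell}, {region}) not in cells/regions")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def get(self, cell: str, region: str) -> RegionCellData | None:
        return self.data.get((cell, region))

    def n_cpgs(self) -> int:
        return sum(len(v) for v in self.data.values())

    def rate_matrix(self) -> np.ndarray:
        """N x M matrix of per-(cell, region) mean methylation states.

        Uncovered entries are NaN; useful for initialisation and for the
        rate-based baselines.
        """
        mat = np.full((self.n_cells, self.n_regions), np.nan)
        ridx = {r: j for j, r in enumerate(self.region_ids)}
        cidx = {c: i for i, c in enumerate(self.cells)}
        for (cell, region), rcd in self.data.items():
            if len(rcd):
                mat[cidx[cell], ridx[region]] = rcd.states.mean()
        return mat

    def subset_regions(self, region_ids: Iterable[str]) -> "MethylomeDataset":
        keep = set(region_ids)
        regions = [r for r in self.regions if r.region_id in keep]
        data = {k: v for k, v in self.data.items() if k[1] in keep}
        if not regions:
            raise EmptyDatasetError("no regions left after subsetting")
        return MethylomeDataset(self.cells, regions, data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeDataset):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.regions == other.regions
            and self.data == other.data
        )


_DIALECT_COLUMNS = {
    "counts": ["chromosome", "position", "met_reads", "total_reads"],
    "rates": ["chromosome", "position", "rate"],
    "binary": ["chromosome", "position", "state"],
}


def read_cell_calls(path: str | Path, dialect: str = "counts") -> pd.DataFrame:
    """Read one cell's tab-separated methylation calls and binarise them.

    Positions are 1-based (Bismark convention).  Duplicate records at one
    position have their read counts summed before binarisation (they
    represent split count lines).  The methylation ratio is thresholded at
    0.5: above -> state 1, below -> state 0, exactly 0.5 (hemi-methylated)
    -> dropped.

    Returns a DataFrame with columns ``chromosome, position, state`` sorted
    by (chromosome, position).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECT_COLUMNS[dialect]
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=cols, comment="#", dtype={0: str}
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed call file {path}: {exc}") from exc
    for col in cols[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df["position"].isna().any():
        line = int(df["position"].isna().idxmax()) + 1
        raise ValueError(f"{path}: missing position at line {line}")

    if dialect == "counts":
        if (df["total_reads"] < 1).any():
            raise ValueError(f"{path}: total_reads must be >= 1")
        if (df["met_reads"] > df["total_reads"]).any() or (df["met_reads"] < 0).any():
            raise ValueError(f"{path}: met_reads must satisfy 0 <= met <= total")
        df = (
            df.groupby(["chromosome", "position"], as_index=False)[
                ["met_reads", "total_reads"]
            ].sum()
        )
        rate = df["met_reads"] / df["total_reads"]
    elif dialect == "rates":
        if ((df["rate"] < 0) | (df["rate"] > 1)).any():
            raise ValueError(f"{path}: rates must lie in [0, 1]")
        df = df.groupby(["chromosome", "position"], as_index=False)["rate"].mean()
        rate = df["rate"]
    else:  # binary
        if not df["state"].isin((0, 1)).all():
            raise ValueError(f"{path}: binary states must be 0 or 1")
        df = df.groupby(["chromosome", "position"], as_index=False)["state"].mean()
        rate = df["state"].astype(float)

    keep = rate != 0.5
    out = df.loc[keep, ["chromosome", "position"]].copy()
    out["state"] = (rate[keep] > 0.5).astype(np.int8)
    out["position"] = out["position"].astype(np.int64)
    return out.sort_values(["chromosome", "position"], ignore_index=True)


def read_annotations(
    path: str | Path, fmt: str = "bed", window: int | None = None
) -> list[RegionAnnotation]:
    """Read region annotations from BED (0-based half-open) or a TSS table.

    The TSS table is tab-separated ``chrom  anchor  strand  region_id`` with
    1-based anchors and requires ``window``: each region is anchor +/- window.
    BED coordinates are converted to 1-based inclusive at this boundary.
    """
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 3:
            raise ValueError("BED file needs at least 3 columns")
        regions = []
        for i, row in df.iterrows():
            name = str(row[3]) if df.shape[1] > 3 else f"region_{i}"
            strand = str(row[5]) if df.shape[1] > 5 else "."
            start1 = int(row[1]) + 1
            end1 = int(row[2])
            regions.append(
                RegionAnnotation(
                    region_id=name,
                    chromosome=str(row[0]),
                    start=start1,
                    end=end1,
                    strand=strand if strand in "+-" else ".",
                )
            )
        return regions
    if fmt == "tss":
        if window is None or window <= 0:
            raise ValueError("TSS annotations require a positive window")
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chromosome", "anchor", "strand", "region_id"],
            comment="#",
            dtype={"chromosome": str, "region_id": str},
        )
        return [
            RegionAnnotation(
                region_id=str(r.region_id),
                chromosome=str(r.chromosome),
                start=int(r.anchor) - window,
                end=int(r.anchor) + window,
                strand=str(r.strand),
                anchor=int(r.anchor),
            )
            for r in df.itertuples()
        ]
    raise ValueError(f"unknown annotation format {fmt!r}")


def _scale_positions(
    positions: np.ndarray, region: RegionAnnotation, window: int | None
) -> np.ndarray:
    if window is not None:
        rel = (positions - region.anchor) / float(window)
    else:
        # affine map of [start, end] onto [-1, 1]
        rel = 2.0 * (positions - region.start) / (region.end - region.start) - 1.0
    if region.strand == "-":
        rel = -rel
    return np.clip(rel, -1.0, 1.0)


def build_regions(
    calls: Mapping[str, pd.DataFrame],
    annotations: list[RegionAnnotation],
    window: int | None = None,
) -> MethylomeDataset:
    """Map binarised calls into regions with scaled relative coordinates.

    ``calls`` maps cell id -> output of :func:`read_cell_calls`.  When
    ``window`` is given, a CpG belongs to a region iff it lies within
    anchor +/- window and scales as (pos - anchor)/window; otherwise region
    intervals map affinely onto [-1, 1].  Minus-strand positions are negated
    so profiles always read 5'->3'.  CpGs outside every region are dropped.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    if window is not None and window <= 0:
        raise ValueError("window must be positive")
    data: dict[tuple[str, str], RegionCellData] = {}
    for cell, df in calls.items():
        for chrom, sub in df.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            states = sub["state"].to_numpy()
            for region in annotations:
                if region.chromosome != str(chrom):
                    continue
                if window is not None:
                    lo, hi = region.anchor - window, region.anchor + window
                else:
                    lo, hi = region.start, region.end
                i0, i1 = np.searchsorted(pos, [lo, hi + 1])
                if i1 <= i0:
                    continue
                rel = _scale_positions(pos[i0:i1].astype(float), region, window)
                order = np.argsort(rel)
                data[(cell, region.region_id)] = RegionCellData(
                    positions=rel[order], states=states[i0:i1][order]
                )
    return MethylomeDataset(list(calls.keys()), annotations, data)


def filter_regions(
    dataset: MethylomeDataset,
    min_cell_frac: float = 0.5,
    min_cpgs: int = 10,
    require_variability: bool = True,
    coverage_mode: str = "per_cell",
    variability_tol: float = 0.0,
) -> MethylomeDataset:
    """Keep regions with sufficient cross-cell coverage and variability.

    A cell "covers" a region iff it has at least ``min_cpgs`` observed CpGs
    there (``coverage_mode='per_cell'``); with ``'pooled'`` the CpG minimum
    applies to the union over cells while the cell fraction counts cells
    with any observation.  A region is retained iff covered by at least
    ``min_cell_frac`` of cells and, if ``require_variability``, the sample
    variance of per-cell mean rates exceeds ``variability_tol`` (default:
    drop only regions whose covering cells all have identical mean rate —
    such homogeneous regions carry no clustering information).
    """
    if not 0 < min_cell_frac <= 1:
        raise ValueError("min_cell_frac must be in (0, 1]")
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    if coverage_mode not in ("per_cell", "pooled"):
        raise ValueError("coverage_mode must be 'per_cell' or 'pooled'")
    n = dataset.n_cells
    kept = []
    for region in dataset.regions:
        rid = region.region_id
        entries = [
            dataset.get(cell, rid) for cell in dataset.cells
            if dataset.get(cell, rid) is not None and len(dataset.get(cell, rid))
        ]
        if coverage_mode == "per_cell":
            covering = [e for e in entries if len(e) >= min_cpgs]
            enough = len(covering) >= min_cell_frac * n
        else:
            covering = entries
            enough = (
                len(entries) >= min_cell_frac * n
                and sum(len(e) for e in entries) >= min_cpgs
            )
        if not enough:
            continue
        if require_variability:
            means = np.array([e.states.mean() for e in covering])
            if means.size < 2 or means.var() <= variability_tol:
                continue
        kept.append(rid)
    if not kept:
        raise EmptyDatasetError(
            f"all {dataset.n_regions} regions removed by filtering "
            f"(min_cell_frac={min_cell_frac}, min_cpgs={min_cpgs}, "
            f"require_variability={require_variability})"
        )
    return dataset.subset_regions(kept)


def split_train_test(
    dataset: MethylomeDataset, train_fraction: float = 0.5, seed: int = 0
) -> tuple[MethylomeDataset, MethylomeDataset]:
    """Partition CpGs uniformly at random within every (cell, region).

    round(train_fraction * I) CpGs go to train (never fewer than 1 when any
    are observed, so every covered block stays fittable); the remainder go
    to test.  The two halves together reconstruct the input exactly.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_data: dict[tuple[str, str], RegionCellData] = {}
    test_data: dict[tuple[str, str], RegionCellData] = {}
    for key in sorted(dataset.data):
        rcd = dataset.data[key]
        n = len(rcd)
        if n == 0:
            continue
        n_train = max(1, int(np.floor(train_fraction * n + 0.5)))
        n_train = min(n_train, n)
        perm = rng.permutation(n)
        tr = np.sort(perm[:n_train])
        te = np.sort(perm[n_train:])
        train_data[key] = RegionCellData(rcd.positions[tr], rcd.states[tr])
        if te.size:
            test_data[key] = RegionCellData(rcd.positions[te], rcd.states[te])
    train = MethylomeDataset(dataset.cells, dataset.regions, train_data)
    test = MethylomeDataset(dataset.cells, dataset.regions, test_data)
    return train, test


def write_dataset(
    dataset: MethylomeDataset, outdir: str | Path, extra_manifest: dict | None = None
) -> None:
    """Write one TSV per cell (`region_id  rel_pos  state`) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells_dir = outdir / "cells"
    cells_dir.mkdir(exist_ok=True)
    for cell in dataset.cells:
        rows = []
        for region in dataset.region_ids:
            rcd = dataset.get(cell, region)
            if rcd is None:
                continue
            for p, s in zip(rcd.positions, rcd.states):
                rows.append(f"{region}\t{p:.10g}\t{int(s)}")
        (cells_dir / f"{cell}.tsv").write_text("\n".join(rows) + ("\n" if rows else ""))
    manifest = {
        "cells": dataset.cells,
        "regions": [r.to_dict() for r in dataset.regions],
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(indir: str | Path) -> MethylomeDataset:
    """Inverse of :func:`write_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    regions = [
        RegionAnnotation(
            region_id=d["region_id"],
            chromosome=d["chromosome"],
            start=d["start"],
            end=d["end"],
            strand=d["strand"],
            anchor=d["anchor"],
        )
        for d in manifest["regions"]
    ]
    data: dict[tuple[str, str], RegionCellData] = {}
    for cell in manifest["cells"]:
        path = indir / "cells" / f"{cell}.tsv"
        text = path.read_text().strip()
        if not text:
            continue
        by_region: dict[str, list[tuple[float, int]]] = {}
        for line in text.splitlines():
            rid, pos, state = line.split("\t")
            by_region.setdefault(rid, []).append((float(pos), int(state)))
        for rid, pairs in by_region.items():
            pairs.sort()
            data[(cell, rid)] = RegionCellData(
                positions=np.array([p for p, _ in pairs]),
                states=np.array([s for _, s in pairs]),
            )
    return MethylomeDataset(manifest["cells"], regions, data)
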