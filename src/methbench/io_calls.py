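"""Reading, writing and assembly of per-CpG methylation call files.

Two widespread call-file dialects are supported:

* ``bismark_cov`` — six tab-separated columns
  (chrom, start, end, methylation %, count-methylated, count-unmethylated)
  with 1-based inclusive coordinates.
* ``bedgraph`` — four or six columns
  (chrom, start, end, methylation % [, count-methylated, count-unmethylated])
  with 0-based half-open coordinates.

Internally every record is normalised to the 0-based position of the cytosine
on the plus strand of the CpG dyad.  The beta value is recomputed from the
read counts whenever counts are present (counts are exact; printed
percentages are rounded).  A beta value is *missing* (NaN) exactly where no
read covers the site — a beta of 0 is a real unmethylated call and is never
conflated with missingness.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

Dialect = Literal["bismark_cov", "bedgraph"]

CALL_COLUMNS = ["chrom", "pos", "beta", "depth", "count_m", "count_u"]


class CallFileParseError(ValueError):
    """A call file row that cannot be interpreted under the declared dialect."""


class CallFileValidationError(ValueError):
    """A call file row that parses but violates a value constraint."""


_CHROM_CHUNKS = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering key: lexicographic with numeric runs compared as
    integers, so ``chr2 < chr10``."""
    parts = _CHROM_CHUNKS.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _sort_frame(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def _is_sorted(df: pd.DataFrame) -> bool:
    if len(df) < 2:
        return True
    key = [(chrom_sort_key(c), p) for c, p in zip(df["chrom"], df["pos"])]
    return all(a <= b for a, b in zip(key, key[1:]))


@dataclass(frozen=True)
class RunMeta:
    """Identity of one processing run: which workflow produced it, from which
    sequencing protocol, on which sample."""

    workflow: str
    protocol: str
    sample: str
    condition: str | None = None  # "tumor" | "normal" when known

    @property
    def run_id(self) -> str:
        return f"{self.workflow}|{self.protocol}|{self.sample}"


@dataclass
class MethylationCallSet:
    """Per-CpG beta values and read depths for one processing run.

    ``df`` holds columns chrom (str), pos (int, 0-based plus-strand cytosine),
    beta (float in [0,1], NaN where depth is 0), depth (float; NaN only when
    the source dialect carried no counts), count_m / count_u (float, NaN when
    unknown).  Rows are sorted by (chrom, pos) without duplicates.
    """

    df: pd.DataFrame
    meta: RunMeta | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"call-set frame lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_depth(self) -> bool:
        return not self.df["depth"].isna().any()

    def validate(self) -> None:
        df = self.df
        beta = df["beta"].to_numpy()
        depth = df["depth"].to_numpy()
        defined = ~np.isnan(beta)
        if np.any((beta[defined] < 0) | (beta[defined] > 1)):
            raise CallFileValidationError("beta outside [0, 1]")
        with np.errstate(invalid="ignore"):
            if np.any(depth[~np.isnan(depth)] < 0):
                raise CallFileValidationError("negative depth")
        zero_depth = depth == 0
        if np.any(defined & zero_depth):
            raise CallFileValidationError("beta defined at zero-depth site")
        if df.duplicated(["chrom", "pos"]).any():
            raise CallFileValidationError("duplicate (chrom, pos)")
        if not _is_sorted(df):
            raise CallFileValidationError("sites not sorted by (chrom, pos)")

    def sites(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[["chrom", "pos"]])


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_call_file(
    path: str | Path,
    dialect: Dialect,
    meta: RunMeta | None = None,
) -> MethylationCallSet:
    """Parse a methylation call file into a :class:`MethylationCallSet`.

    Coordinates are normalised to 0-based cytosine positions; beta is
    recomputed from counts when the file carries them.  Unsorted input is
    sorted on load with a logged notice; a malformed row raises
    :class:`CallFileParseError` naming the offending line.
    """
    if dialect not in ("bismark_cov", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                parsed = _parse_row(fields, dialect)
            except CallFileValidationError:
                raise
            except (ValueError, IndexError) as exc:
                raise CallFileParseError(
                    f"{path}: line {lineno}: cannot parse {line!r} as {dialect}"
                ) from exc
            rows.append(parsed)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    if not _is_sorted(df):
        logger.info("%s: rows not coordinate-sorted; sorting on load", path)
        df = _sort_frame(df)
    calls = MethylationCallSet(df, meta=meta)
    calls.validate()
    return calls


def _parse_row(fields: Sequence[str], dialect: Dialect) -> tuple:
    chrom = fields[0]
    start = int(fields[1])
    _end = int(fields[2])
    pct = float(fields[3])
    if not 0.0 <= pct <= 100.0:
        raise CallFileValidationError(
            f"methylation % {pct} outside [0, 100] at {chrom}:{start}"
        )
    pos = start - 1 if dialect == "bismark_cov" else start
    if pos < 0:
        raise CallFileValidationError(f"negative position at {chrom}:{start}")
    if len(fields) >= 6:
        m = int(fields[4])
        u = int(fields[5])
        if m < 0 or u < 0:
            raise CallFileValidationError(f"negative count at {chrom}:{start}")
        depth = m + u
        beta = m / depth if depth > 0 else np.nan
        return (chrom, pos, beta, float(depth), float(m), float(u))
    # four-column bedGraph: no counts, depth unknown
    return (chrom, pos, pct / 100.0, np.nan, np.nan, np.nan)


def write_call_file(
    calls: MethylationCallSet, path: str | Path, dialect: Dialect
) -> Path:
    """Write a call set in the requested dialect (gzip if path ends in .gz).

    ``bismark_cov`` requires counts; a four-column bedGraph is emitted when
    counts are unavailable.
    """
    path = Path(path)
    # call files list covered sites only: zero-depth (undefined-beta) rows
    # are represented by absence
    df = calls.df[~calls.df["beta"].isna()]
    has_counts = not df["count_m"].isna().any()
    if dialect == "bismark_cov" and not has_counts:
        raise ValueError("bismark_cov output requires methylated/unmethylated counts")
    with _open_text(path, "wt") as fh:
        for row in df.itertuples(index=False):
            pct = row.beta * 100.0
            if dialect == "bismark_cov":
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6f}\t"
                    f"{int(row.count_m)}\t{int(row.count_u)}\n"
                )
            elif has_counts:
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.6f}\t"
                    f"{int(row.count_m)}\t{int(row.count_u)}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.6f}\n")
    return path


def collapse_strands(
    calls: MethylationCallSet, mode: Literal["merge", "plus_only"] = "merge"
) -> MethylationCallSet:
    """Collapse the two symmetric cytosine calls of each CpG dyad.

    Records at positions p and p+1 on the same chromosome are treated as one
    dyad (plus-strand C at p, minus-strand C at p+1).  In ``merge`` mode the
    counts are summed (beta becomes the depth-weighted mean when counts are
    unavailable); in ``plus_only`` mode only the plus-strand record is kept.
    Runs of consecutive positions are paired greedily left to right.
    """
    df = calls.df
    n = len(df)
    if n == 0:
        return MethylationCallSet(df.copy(), meta=calls.meta)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    adjacent = (chrom[:-1] == chrom[1:]) & (pos[1:] == pos[:-1] + 1)
    partner = np.full(n, -1, dtype=np.int64)  # index of minus-strand mate
    is_mate = np.zeros(n, dtype=bool)
    taken = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(adjacent):
        if not taken[i] and not taken[i + 1]:
            partner[i] = i + 1
            is_mate[i + 1] = True
            taken[i] = taken[i + 1] = True
    keep_rows: list[dict] = []
    for i in range(n):
        if partner[i] >= 0:
            j = partner[i]
            if mode == "plus_only":
                keep_rows.append(df.iloc[i].to_dict())
                continue
            a, b = df.iloc[i], df.iloc[j]
            if not (np.isnan(a["count_m"]) or np.isnan(b["count_m"])):
                m = a["count_m"] + b["count_m"]
                u = a["count_u"] + b["count_u"]
                depth = m + u
                beta = m / depth if depth > 0 else np.nan
                keep_rows.append(
                    dict(chrom=a["chrom"], pos=a["pos"], beta=beta,
                         depth=depth, count_m=m, count_u=u)
                )
            else:
                d1 = 0.0 if np.isnan(a["depth"]) else a["depth"]
                d2 = 0.0 if np.isnan(b["depth"]) else b["depth"]
                depth = d1 + d2
                if depth > 0:
                    b1 = 0.0 if np.isnan(a["beta"]) else a["beta"]
                    b2 = 0.0 if np.isnan(b["beta"]) else b["beta"]
                    beta = (b1 * d1 + b2 * d2) / depth
                else:
                    beta = np.nan
                keep_rows.append(
                    dict(chrom=a["chrom"], pos=a["pos"], beta=beta,
                         depth=depth, count_m=np.nan, count_u=np.nan)
                )
        elif not is_mate[i]:  # lone record passes through
            keep_rows.append(df.iloc[i].to_dict())
    out = pd.DataFrame(keep_rows, columns=CALL_COLUMNS)
    out["pos"] = out["pos"].astype(np.int64)
    return MethylationCallSet(out.reset_index(drop=True), meta=calls.meta)


@dataclass
class MethylationMatrix:
    """CpG-by-run beta and depth matrices with a run manifest.

    Rows are indexed by (chrom, pos); columns are run ids.  ``beta`` is NaN
    exactly where the run does not cover the site at the required depth;
    ``depth`` is 0 for sites absent from a run's file.
    """

    beta: pd.DataFrame
    depth: pd.DataFrame
    manifest: pd.DataFrame  # index run_id; columns workflow, protocol, sample, condition

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(self.manifest.index):
            raise ValueError("matrix columns do not match manifest")
        if self.beta.shape != self.depth.shape:
            raise ValueError("beta and depth shapes differ")

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_runs(self) -> int:
        return self.beta.shape[1]

    def runs_where(self, **conditions: str) -> list[str]:
        """Run ids whose manifest entries match all given field values."""
        mask = pd.Series(True, index=self.manifest.index)
        for k, v in conditions.items():
            mask &= self.manifest[k] == v
        return list(self.manifest.index[mask])


def assemble_matrix(
    call_sets: Sequence[MethylationCallSet],
    universe: pd.MultiIndex | Iterable[tuple[str, int]] | str = "union",
) -> MethylationMatrix:
    """Stack strand-collapsed call sets into a site-by-run matrix.

    ``universe`` is either an explicit list of (chrom, pos) sites or
    ``"union"`` for the sorted union of all sites seen in any run.
    """
    if not call_sets:
        raise ValueError("no call sets to assemble")
    ids = []
    for cs in call_sets:
        if cs.meta is None:
            raise ValueError("every call set needs RunMeta to be assembled")
        ids.append(cs.meta.run_id)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate (workflow, protocol, sample) runs: {dupes}")

    if isinstance(universe, str):
        if universe != "union":
            raise ValueError("universe must be site list or 'union'")
        all_sites = pd.concat(
            [cs.df[["chrom", "pos"]] for cs in call_sets]
        ).drop_duplicates()
        all_sites = _sort_frame(all_sites.assign(beta=np.nan))[["chrom", "pos"]]
        index = pd.MultiIndex.from_frame(all_sites)
    elif isinstance(universe, pd.MultiIndex):
        index = universe
    else:
        index = pd.MultiIndex.from_tuples(list(universe), names=["chrom", "pos"])

    beta = pd.DataFrame(index=index, columns=ids, dtype=float)
    depth = pd.DataFrame(0.0, index=index, columns=ids)
    for cs, rid in zip(call_sets, ids):
        s = cs.df.set_index(["chrom", "pos"])
        common = index.intersection(s.index)
        beta.loc[common, rid] = s.loc[common, "beta"]
        d = s.loc[common, "depth"]
        depth.loc[common, rid] = d.fillna(0.0)
    manifest = pd.DataFrame(
        [
            dict(workflow=cs.meta.workflow, protocol=cs.meta.protocol,
                 sample=cs.meta.sample, condition=cs.meta.condition)
            for cs in call_sets
        ],
        index=ids,
    )
    return MethylationMatrix(beta=beta, depth=depth, manifest=manifest)


def filter_by_depth(
    matrix: MethylationMatrix, min_depth: int, drop_empty_sites: bool = False
) -> MethylationMatrix:
    """Hide beta values supported by fewer than ``min_depth`` reads.

    A site with depth >= min_depth is retained ("below threshold" excluded);
    depth values themselves are preserved so the operation is idempotent and
    monotone in ``min_depth``.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    beta = matrix.beta.where(matrix.depth >= min_depth)
    depth = matrix.depth.copy()
    if drop_empty_sites:
        keep = beta.notna().any(axis=1)
        beta, depth = beta.loc[keep], depth.loc[keep]
    return MethylationMatrix(beta=beta, depth=depth, manifest=matrix.manifest.copy())


# ---------------------------------------------------------------------------
# Run manifests

MANIFEST_COLUMNS = ["path", "dialect", "workflow", "protocol", "sample", "condition"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a run manifest (TSV or YAML list of records)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            records = yaml.safe_load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def load_runs(manifest: pd.DataFrame, base_dir: str | Path | None = None,
              collapse: str = "merge") -> list[MethylationCallSet]:
    """Read every run listed in a manifest, strand-collapsing each one."""
    base = Path(base_dir) if base_dir is not None else None
    out = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if base is not None and not p.is_absolute():
            p = base / p
        meta = RunMeta(row.workflow, row.protocol, row.sample,
                       None if pd.isna(row.condition) else row.condition)
        cs = read_call_file(p, row.dialect, meta=meta)
        out.append(collapse_strands(cs, mode=collapse))
    return out
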