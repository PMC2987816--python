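"""Readers and writers for the pipeline's plain-text formats.

All tabular I/O goes through pandas.  Internal coordinates are 1-based
inclusive; ``.bedgraph``/``.bg``/``.bed`` inputs are converted from 0-based
half-open on ingestion.  See the README for one worked example per format.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    GenomicWindowGrid,
    GenotypeTable,
    MethylationMatrix,
    Region,
    SampleMetadata,
    SnpContext,
)

__all__ = [
    "read_methylation_tracks",
    "read_genotypes",
    "read_metadata",
    "read_regions",
    "read_snp_table",
    "write_results",
    "read_results",
    "write_methylation_tracks",
    "write_genotypes",
    "write_metadata",
]

_BED_SUFFIXES = {".bedgraph", ".bg", ".bed"}


def _read_track(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "score"],
        comment="#",
        dtype={"chrom": str},
    )
    if path.suffix.lower() in _BED_SUFFIXES:
        df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    bad = df.index[(df["score"] < 0) | (df["score"] > 1) | df["score"].isna()]
    if len(bad):
        line = int(bad[0]) + 1
        raise ValueError(
            f"{path}, line {line}: methylation score {df.loc[bad[0], 'score']} outside [0, 1]"
        )
    return df


def read_methylation_tracks(
    paths: list[str | os.PathLike],
    grid_spec: GenomicWindowGrid | None = None,
    sample_ids: list[str] | None = None,
) -> MethylationMatrix:
    """Read per-sample window tracks onto a single shared grid.

    Each file is 4 columns (chrom, start, end, score), TSV 1-based inclusive
    or BEDGRAPH (by extension) 0-based half-open.  Without ``grid_spec`` the
    grid is inferred from the union of windows across samples: absent windows
    become masked, so a repeat-excluded track defines its own mask.
    """
    if not paths:
        raise ValueError("no track files given")
    if sample_ids is None:
        sample_ids = [Path(p).stem for p in paths]
    tracks = [_read_track(p) for p in paths]

    widths = {int(w) for t in tracks for w in (t["end"] - t["start"] + 1).unique()}
    if len(widths) != 1:
        raise ValueError(f"inconsistent window sizes across tracks: {sorted(widths)}")
    wsize = widths.pop()

    chroms = {c for t in tracks for c in t["chrom"].unique()}
    if len(chroms) != 1:
        raise ValueError(f"tracks span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    if grid_spec is None:
        lo = min(int(t["start"].min()) for t in tracks)
        hi = max(int(t["end"].max()) for t in tracks)
        if (hi - lo + 1) % wsize:
            raise ValueError("track windows are not aligned to a common grid")
        n = (hi - lo + 1) // wsize
        grid = GenomicWindowGrid(chrom, lo, n, wsize, mask=np.ones(n, dtype=bool))
    else:
        grid = grid_spec
        if grid.chrom != chrom or grid.window_size_bp != wsize:
            raise ValueError("tracks do not match the supplied grid")

    scores = np.full((len(tracks), grid.n_windows), np.nan)
    seen = np.zeros(grid.n_windows, dtype=bool)
    for i, t in enumerate(tracks):
        offsets = (t["start"].to_numpy() - grid.start)
        if ((offsets < 0) | (offsets % grid.window_size_bp != 0)).any():
            raise ValueError(f"{paths[i]}: windows not aligned to the grid")
        idx = offsets // grid.window_size_bp
        if (idx >= grid.n_windows).any():
            raise ValueError(f"{paths[i]}: windows beyond the grid")
        scores[i, idx] = t["score"].to_numpy()
        seen[idx] = True
    if grid_spec is None:
        grid.mask = ~seen
    return MethylationMatrix(grid, list(sample_ids), scores)


def write_methylation_tracks(matrix: MethylationMatrix, out_dir: str | os.PathLike) -> list[Path]:
    """One 4-column TSV per sample (unmasked windows only); round-trips
    through :func:`read_methylation_tracks`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = matrix.grid
    keep = ~grid.mask
    starts = grid.start + np.flatnonzero(keep) * grid.window_size_bp
    ends = starts + grid.window_size_bp - 1
    paths = []
    for i, sid in enumerate(matrix.sample_ids):
        df = pd.DataFrame(
            {"chrom": grid.chrom, "start": starts, "end": ends, "score": matrix.scores[i, keep]}
        )
        p = out_dir / f"{sid}.tsv"
        df.to_csv(p, sep="\t", header=False, index=False, float_format="%.9g")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# genotypes

_DOSAGE_CODES = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, ".": np.nan, "": np.nan}


def _cell_to_dosage(cell: str, snp: str, common: str, rare: str) -> float:
    cell = str(cell).strip()
    if cell.upper() in ("NA", ".", "", "NAN"):
        return np.nan
    if cell in _DOSAGE_CODES:
        return _DOSAGE_CODES[cell]
    if len(cell) == 2:  # allele pair, e.g. "AC"
        d = 0.0
        for a in cell.upper():
            if a == rare:
                d += 1.0
            elif a != common:
                raise ValueError(f"{snp}: unknown allele symbol {a!r} in {cell!r}")
        return d
    raise ValueError(f"{snp}: cannot parse genotype cell {cell!r}")


def read_genotypes(
    path: str | os.PathLike, alleles: dict[str, tuple[str, str]]
) -> GenotypeTable:
    """Read a sample x SNP genotype TSV (header of snp_ids, first column
    sample_id).  Cells are dosage codes 0/1/2 or allele pairs ("AA", "AC",
    "CC"), converted using each SNP's declared (common, rare) alleles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_col = df.columns[0]
    sample_ids = df[sample_col].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample_id")
    snp_ids = list(df.columns[1:])
    missing = [s for s in snp_ids if s not in alleles]
    if missing:
        raise ValueError(f"{path}: no allele declaration for {missing}")
    dosage = np.empty((len(sample_ids), len(snp_ids)))
    for j, snp in enumerate(snp_ids):
        common, rare = alleles[snp]
        dosage[:, j] = [_cell_to_dosage(c, snp, common.upper(), rare.upper()) for c in df[snp]]
    return GenotypeTable(sample_ids, snp_ids, dosage, {s: alleles[s] for s in snp_ids})


def write_genotypes(table: GenotypeTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(table.dosage, columns=table.snp_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%g", na_rep="NA")


# ---------------------------------------------------------------------------
# metadata / regions / SNP contexts


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    """TSV with columns sample_id, status (0/1), age, sex (optional)."""
    df = pd.read_csv(path, sep="\t")
    sex = df["sex"].astype(str).tolist() if "sex" in df.columns else None
    return SampleMetadata(
        df["sample_id"].astype(str).tolist(),
        df["status"].to_numpy(float),
        df["age"].to_numpy(float),
        sex,
    )


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"sample_id": meta.sample_ids, "status": meta.status.astype(int), "age": meta.age}
    )
    if meta.sex is not None:
        df["sex"] = meta.sex
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_regions(path: str | os.PathLike) -> list[Region]:
    """Region TSV (chrom, start, end[, label]; 1-based inclusive) or BED
    (0-based half-open, by .bed extension)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    is_bed = path.suffix.lower() == ".bed"
    # tolerate a header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    out = []
    for _, row in df.iterrows():
        start = int(row[1]) + (1 if is_bed else 0)
        label = str(row[3]) if len(df.columns) > 3 else ""
        out.append(Region(str(row[0]), start, int(row[2]), label))
    return out


def read_snp_table(path: str | os.PathLike) -> list[SnpContext]:
    """TSV with columns snp_id, chrom, pos, left_flank, allele_a, allele_b,
    right_flank, ancestral (``.`` or empty = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        anc = r.get("ancestral")
        anc = None if anc is None or str(anc) in (".", "", "nan", "NA") else str(anc).upper()
        out.append(
            SnpContext(
                snp_id=str(r["snp_id"]),
                chrom=str(r.get("chrom", "")),
                position=int(r["pos"]),
                left_flank=str(r["left_flank"]).upper(),
                allele_a=str(r["allele_a"]).upper(),
                allele_b=str(r["allele_b"]).upper(),
                right_flank=str(r["right_flank"]).upper(),
                ancestral=anc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# result tables


def write_results(table: pd.DataFrame, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a result table deterministically (fixed column order, >= 6
    significant digits) so it round-trips losslessly via :func:`read_results`."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.9g")
    elif format == "json":
        payload = {
            "columns": list(table.columns),
            "rows": json.loads(table.to_json(orient="values", double_precision=12)),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | os.PathLike, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown format {format!r}")
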