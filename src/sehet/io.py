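"""Readers and writers for the on-disk formats.

BED (3-6 columns, 0-based half-open), MatrixMarket matrices with
barcodes/features sidecars, foci-count CSVs, and provenance JSON.  All
genomic coordinates are 0-based half-open internally; conversions (none
needed for BED) happen only at I/O boundaries.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = ["read_bed", "write_bed", "read_mtx", "write_mtx",
           "read_foci_csv", "write_foci_csv", "write_provenance"]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """Read BED3-BED6; track/browser/header lines are skipped.

    The score column carries the signal when present.  Raises
    :class:`BedParseError` with the offending line number.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith(("track", "browser", "#"))):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"line {lineno}: {e}") from None
            if start >= end or start < 0:
                raise BedParseError(
                    f"line {lineno}: invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = float(parts[4])
            if len(parts) > 5:
                row["strand"] = parts[5]
            ncols = max(ncols or 0, len(parts))
            rows.append(row)
    df = pd.DataFrame(rows, columns=BED_COLUMNS[:ncols or 3])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write BED with whichever of the 6 canonical columns are present."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            vals = []
            for c, v in zip(cols, row):
                if c in ("start", "end"):
                    vals.append(str(int(v)))
                elif c == "score":
                    vals.append(f"{v:g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def write_mtx(adata: ad.AnnData, outdir) -> None:
    """MatrixMarket coordinate matrix + barcodes.tsv + features.tsv.

    The matrix is written features x cells (the common sparse
    convention); zero rows/columns survive the round trip because the
    dimensions live in the header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(
        np.asarray(adata.X))
    scio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    adata.obs.index.to_series().to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    adata.var.index.to_series().to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False)
    adata.obs.to_csv(outdir / "cell_metadata.csv")
    adata.var.to_csv(outdir / "feature_metadata.csv")


def read_mtx(indir) -> ad.AnnData:
    """Inverse of :func:`write_mtx`, with dimension checks."""
    indir = Path(indir)
    X = scio.mmread(str(indir / "matrix.mtx")).T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {X.shape} does not match sidecars "
            f"({len(barcodes)} barcodes x {len(features)} features)")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    var = pd.DataFrame(index=pd.Index(features, name="feature"))
    meta_c = indir / "cell_metadata.csv"
    if meta_c.exists():
        obs = pd.read_csv(meta_c, index_col=0)
    meta_f = indir / "feature_metadata.csv"
    if meta_f.exists():
        var = pd.read_csv(meta_f, index_col=0)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_foci_csv(table: pd.DataFrame, path) -> None:
    table[["cell_id", "dose", "time_min", "foci"]].to_csv(path, index=False)


def read_foci_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "dose", "time_min", "foci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"foci table lacks columns {sorted(missing)}")
    if (df["foci"] < 0).any():
        raise ValueError("negative foci counts")
    return df


def write_provenance(outdir, config: dict, seed: int) -> Path:
    """Drop a provenance JSON (config hash, seed, versions) into outdir."""
    import scipy
    import sklearn

    from . import __version__

    payload = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "versions": {
            "sehet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    path = Path(outdir) / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path
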