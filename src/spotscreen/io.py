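"""Readers and writers for every on-disk format the pipeline touches.

Conventions: spot coordinates are 1-based (x = A/C channel, y = B/D
channel) everywhere on disk; sparse matrices go to Matrix Market
coordinate files with ``spots.tsv`` / ``sgrnas.tsv`` sidecars in canonical
row-major (x, y) spot order; FASTQ is gzip-transparent by extension.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .quant import RegionMask, SpotSgrnaMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_fastq",
    "write_demux_records",
    "read_demux_records",
    "write_region_masks",
    "read_region_masks",
    "read_gmt",
    "write_gmt",
    "write_manifest",
    "sha256_of",
]


def write_matrix(M: SpotSgrnaMatrix, prefix) -> None:
    """Write matrix.mtx + spots.tsv + sgrnas.tsv under ``prefix`` directory."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix / "matrix.mtx"), M.counts.tocoo())
    coords = M.spot_coords()
    if M.tissue is not None:
        tset = M.tissue
        coords = coords.assign(
            tissue=[int((x, y) in tset) for x, y in zip(coords["x"], coords["y"])]
        )
    coords.to_csv(prefix / "spots.tsv", sep="\t", index=False)
    pd.DataFrame({"sgrna": M.sgrnas}).to_csv(
        prefix / "sgrnas.tsv", sep="\t", index=False
    )
    with open(prefix / "dims.json", "w") as fh:
        json.dump({"n_a": M.grid_dims[0], "n_b": M.grid_dims[1],
                   "pitch_um": M.pitch_um}, fh)


def read_matrix(prefix) -> SpotSgrnaMatrix:
    prefix = Path(prefix)
    counts = sparse.csr_matrix(spio.mmread(str(prefix / "matrix.mtx")))
    spots = pd.read_csv(prefix / "spots.tsv", sep="\t")
    sgrnas = tuple(pd.read_csv(prefix / "sgrnas.tsv", sep="\t")["sgrna"])
    with open(prefix / "dims.json") as fh:
        dims = json.load(fh)
    na, nb = int(dims["n_a"]), int(dims["n_b"])
    if counts.shape[0] != na * nb or len(spots) != na * nb:
        raise ValueError("matrix dimensions disagree with sidecar files")
    if counts.shape[1] != len(sgrnas):
        raise ValueError("sgRNA sidecar length disagrees with matrix columns")
    tissue = None
    if "tissue" in spots.columns:
        tissue = frozenset(
            (int(r.x), int(r.y)) for r in spots.itertuples() if r.tissue
        )
    return SpotSgrnaMatrix(
        grid_dims=(na, nb), counts=counts.astype(np.int64), sgrnas=sgrnas,
        tissue=tissue, pitch_um=float(dims.get("pitch_um", 50.0)),
    )


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence) pairs as FASTQ (gzip when path ends .gz).

    Gzip members are written with mtime=0 so identical reads produce
    byte-identical files on every run.
    """
    path = Path(path)
    if path.suffix == ".gz":
        import io as _io

        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                with _io.TextIOWrapper(gz) as fh:
                    for rid, seq in reads:
                        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    else:
        with open(path, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_demux_records(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tx\ty\tsgrna\tumi\tstatus\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.x if r.x else ''}\t{r.y if r.y else ''}\t"
                f"{r.sgrna or ''}\t{r.umi or ''}\t{r.status}\n"
            )


def read_demux_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str})


def write_region_masks(regions, path) -> None:
    rows = [
        {"region_name": r.name, "x": x, "y": y}
        for r in regions
        for x, y in sorted(r.spots)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_masks(path) -> list[RegionMask]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("region_name", sort=True):
        out.append(RegionMask(
            name=str(name),
            spots=frozenset(zip(grp["x"].astype(int), grp["y"].astype(int))),
        ))
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, params: dict, seeds: dict,
                   inputs: dict | None = None, outputs: list | None = None,
                   timestamp: str | None = None) -> dict:
    """Run manifest: parameters, derived seeds, input checksums.

    ``timestamp`` is isolated in its own key so reruns can be compared by
    ignoring it.
    """
    import datetime

    manifest = {
        "stage": stage,
        "params": params,
        "seeds": seeds,
        "inputs": {k: sha256_of(v) for k, v in (inputs or {}).items()},
        "outputs": outputs or [],
        "timestamp": timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
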