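"""Readers and writers: genotype matrices, PLINK bed/bim/fam, coordinates,
habitat polygons, and the CSV/JSON artifacts the CLI emits.

Coordinates are always (longitude, latitude); coordinate files must carry a
``lon,lat`` header so axis order is never guessed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MISSING_CODES = ("NA", "na", "-9", "-9.0", "NaN", "nan", "")


def read_genotype_matrix(
    path: str | Path, missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES
) -> np.ndarray:
    """Delimited genotype matrix (rows = individuals, columns = SNPs).

    Values must be 0/1/2 allele counts; any of ``missing_codes`` becomes NaN.
    Whitespace-, comma- and tab-delimited files are accepted.
    """
    df = pd.read_csv(
        path, sep=None, engine="python", header=None, na_values=list(missing_codes),
        comment="#",
    )
    G = df.to_numpy(dtype=float)
    vals = G[~np.isnan(G)]
    if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{path}: genotype values must be 0, 1, 2 or missing")
    return G


def read_coords(path: str | Path) -> np.ndarray:
    """Two-column coordinate file with a mandatory ``lon,lat`` header."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["lon", "lat"]:
        raise ValueError(
            f"{path}: coordinate file must have header 'lon,lat' "
            "(longitude first; this avoids silent axis swaps)"
        )
    return df.iloc[:, :2].to_numpy(dtype=float)


def read_polygon(path: str | Path) -> np.ndarray:
    """Habitat outer ring: 'lon lat' per line, or a GeoJSON Polygon."""
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        obj = json.loads(text)
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        if obj.get("type") != "Polygon":
            raise ValueError(f"{path}: GeoJSON must contain a Polygon")
        return np.asarray(obj["coordinates"][0], dtype=float)
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append([float(parts[0]), float(parts[1])])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam (SNP-major 2-bit codes; no reader library required)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> count of the bim A1 allele (01 = missing)
_BED_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK bed/bim/fam triple into (genotypes, bim, fam).

    Genotypes are returned as an (individuals x SNPs) float matrix counting
    the bim A1 allele, with NaN for missing calls.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    n, p = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise ValueError(f"{prefix}.bed: unexpected file size")
    body = body.reshape(p, bytes_per_snp)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11  # p x bytes x 4
    codes = codes.reshape(p, -1)[:, :n]
    return _BED_CODE[codes].T.copy(), bim, fam


def write_plink(prefix: str | Path, genotypes: np.ndarray) -> None:
    """Write a minimal bed/bim/fam triple (synthetic metadata) for testing."""
    prefix = Path(prefix)
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    inverse = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.full(G.shape, 1, dtype=np.uint8)  # missing
    for val, code in inverse.items():
        codes[G == val] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((pad, p), dtype=np.uint8)], axis=0)
    packed = (
        codes.T.reshape(p, -1, 4) << (np.arange(4, dtype=np.uint8) * 2)
    ).sum(axis=2).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())
    bim = pd.DataFrame(
        {"chrom": 1, "snp": [f"snp{j}" for j in range(p)], "cm": 0,
         "pos": np.arange(1, p + 1), "a1": "A", "a2": "T"}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)],
         "father": 0, "mother": 0, "sex": 0, "phenotype": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# output artifacts
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_nodes_csv(path: str | Path, graph, n_samples_per_node=None) -> None:
    counts = np.zeros(graph.n_nodes, dtype=int)
    if n_samples_per_node is not None:
        counts = np.asarray(n_samples_per_node, dtype=int)
    pd.DataFrame(
        {
            "node_id": np.arange(graph.n_nodes),
            "lon": graph.node_coords[:, 0],
            "lat": graph.node_coords[:, 1],
            "n_samples": counts,
        }
    ).to_csv(path, index=False)


def write_edges_csv(path: str | Path, fit) -> None:
    fit.to_dataframe().to_csv(path, index=False)


def write_graph_edges_csv(path: str | Path, graph) -> None:
    pd.DataFrame(
        {
            "edge_id": np.arange(graph.n_edges),
            "node_a": graph.edges[:, 0],
            "node_b": graph.edges[:, 1],
        }
    ).to_csv(path, index=False)


def write_metadata_json(path: str | Path, metadata: dict) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str))
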