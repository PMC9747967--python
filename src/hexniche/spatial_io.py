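"""Reading, validating and writing Visium-dialect datasets.

A dataset directory holds one subdirectory per sample with the familiar
triplet ``matrix.mtx`` (genes x spots), ``features.tsv`` and
``barcodes.tsv`` plus a ``tissue_positions_list.csv`` in the Space Ranger
v1 dialect (headerless ``barcode,in_tissue,array_row,array_col,pxl_row,
pxl_col``; a headered variant is auto-detected), and two top-level tables:
``annotation.csv`` (sample_id,barcode,layer) and ``metadata.csv``
(sample_id,patient_id,project_id,disease,condition).

Genes are harmonized across samples by symbol (outer union, zero fill);
duplicate symbols within a sample are made unique by suffixing.  All
geometry downstream operates on the 0-based integer array indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .hexcluster import DensityCluster, HexCoord

__all__ = [
    "LAYER_VOCAB",
    "EPIDERMIS_LAYERS",
    "DERMIS_LAYERS",
    "SpotDataset",
    "DatasetError",
    "load_dataset",
    "save_dataset",
    "write_cluster_table",
]

LAYER_VOCAB = (
    "upper epidermis",
    "middle epidermis",
    "basal epidermis",
    "junction",
    "dermis 1",
    "dermis 2",
    "dermis 3",
    "dermis 4",
    "dermis 5",
    "dermis 6",
    "dermis 7",
    "excluded",
)
EPIDERMIS_LAYERS = ("upper epidermis", "middle epidermis", "basal epidermis")
DERMIS_LAYERS = tuple(f"dermis {i}" for i in range(1, 8))

DISEASES = ("LP", "AD", "Pso", "none")
CONDITIONS = ("lesional", "non-lesional")

SPOT_COLUMNS = ["sample_id", "barcode", "in_tissue", "array_row", "array_col", "layer"]
META_COLUMNS = ["sample_id", "patient_id", "project_id", "disease", "condition"]


class DatasetError(ValueError):
    """Fatal dataset assembly/validation failure."""


@dataclass
class SpotDataset:
    """Spot-by-gene raw UMI counts joined to coordinates, layer
    annotations and sample metadata.

    ``counts`` is a CSR matrix of shape (n_spots, n_genes) aligned with
    ``spots`` rows and ``genes``; ``spots`` carries sample_id, barcode,
    in_tissue, array_row, array_col and layer; ``meta`` is indexed by
    sample_id.
    """

    counts: sparse.csr_matrix
    genes: pd.Index
    spots: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.spots["sample_id"].unique())

    def gene_index(self, symbol: str) -> int:
        idx = self.genes.get_indexer([symbol])
        if idx[0] < 0:
            raise DatasetError(f"gene {symbol!r} not present in dataset")
        return int(idx[0])

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_spots(self, mask: np.ndarray) -> "SpotDataset":
        mask = np.asarray(mask, dtype=bool)
        return SpotDataset(
            counts=self.counts[mask],
            genes=self.genes,
            spots=self.spots.loc[mask].reset_index(drop=True),
            meta=self.meta,
        )

    def subset_genes(self, mask: np.ndarray) -> "SpotDataset":
        mask = np.asarray(mask, dtype=bool)
        return SpotDataset(
            counts=self.counts[:, mask].tocsr(),
            genes=self.genes[mask],
            spots=self.spots,
            meta=self.meta,
        )

    def coord_map(self, sample_id: str) -> dict[HexCoord, int]:
        """Map (array_row, array_col) -> row index, for one sample."""
        sub = self.spots[self.spots["sample_id"] == sample_id]
        return {
            (int(r), int(c)): int(i)
            for i, r, c in zip(sub.index, sub["array_row"], sub["array_col"])
        }

    def validate(self) -> None:
        sp = self.spots
        if list(sp.columns) != SPOT_COLUMNS:
            raise DatasetError(f"spot table must have columns {SPOT_COLUMNS}")
        if self.counts.shape != (len(sp), len(self.genes)):
            raise DatasetError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(sp)} spots x {len(self.genes)} genes"
            )
        if self.counts.nnz:
            data = self.counts.data
            if (data < 0).any() or np.any(data != np.round(data)):
                raise DatasetError("counts must be nonnegative integers")
        if len(sp):
            parity = (sp["array_row"] + sp["array_col"]) % 2
            if (parity != 0).any():
                bad = sp.loc[parity != 0, ["sample_id", "barcode"]]
                offenders = ", ".join(
                    f"{s}:{b}" for s, b in bad.itertuples(index=False)
                )
                raise DatasetError(
                    f"array parity violated (row+col must be even) for: {offenders}"
                )
            if sp.duplicated(["sample_id", "barcode"]).any():
                raise DatasetError("(sample_id, barcode) pairs must be unique")
            if sp.duplicated(["sample_id", "array_row", "array_col"]).any():
                raise DatasetError("(sample_id, array_row, array_col) must be unique")
            unknown = set(sp["layer"]) - set(LAYER_VOCAB)
            if unknown:
                raise DatasetError(f"unknown layer labels: {sorted(unknown)}")
        if self.genes.duplicated().any():
            raise DatasetError("gene symbols must be unique after harmonization")
        missing_meta = set(sp["sample_id"]) - set(self.meta.index)
        if missing_meta:
            raise DatasetError(f"samples missing from metadata: {sorted(missing_meta)}")
        if self.meta.index.duplicated().any():
            raise DatasetError("duplicate sample_id in metadata")
        bad_disease = set(self.meta["disease"]) - set(DISEASES)
        if bad_disease:
            raise DatasetError(f"unknown disease values: {sorted(bad_disease)}")
        bad_cond = set(self.meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DatasetError(f"unknown condition values: {sorted(bad_cond)}")


def _dedupe(symbols: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _read_features(path: Path) -> list[str]:
    symbols = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            symbols.append(parts[1] if len(parts) >= 2 else parts[0])
    return _dedupe(symbols)


def _read_positions(path: Path) -> pd.DataFrame:
    """Read tissue_positions_list.csv, sniffing for an optional header."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        return pd.DataFrame(
            columns=["barcode", "in_tissue", "array_row", "array_col"]
        )
    fields = first.split(",")
    has_header = len(fields) >= 2 and not fields[1].strip().lstrip("-").isdigit()
    df = pd.read_csv(path, header=0 if has_header else None)
    df = df.iloc[:, :4]
    df.columns = ["barcode", "in_tissue", "array_row", "array_col"]
    df["barcode"] = df["barcode"].astype(str)
    for col in ("in_tissue", "array_row", "array_col"):
        df[col] = df[col].astype(int)
    return df


def _require(path: Path) -> Path:
    if not path.exists():
        raise DatasetError(f"required file missing: {path}")
    return path


def load_dataset(directory: str | Path) -> SpotDataset:
    """Assemble a validated :class:`SpotDataset` from a dataset directory.

    Every subdirectory containing a ``matrix.mtx`` is treated as one
    sample, keyed by its directory name.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DatasetError(f"dataset directory not found: {directory}")
    meta_path = _require(directory / "metadata.csv")
    ann_path = _require(directory / "annotation.csv")

    meta = pd.read_csv(meta_path, dtype=str)
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata.csv missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")

    ann = pd.read_csv(ann_path, dtype=str)
    for col in ("sample_id", "barcode", "layer"):
        if col not in ann.columns:
            raise DatasetError(f"annotation.csv missing column {col!r}")
    unknown = set(ann["layer"]) - set(LAYER_VOCAB)
    if unknown:
        raise DatasetError(f"unknown layer labels in annotation.csv: {sorted(unknown)}")
    ann_map = {
        (s, b): l
        for s, b, l in zip(ann["sample_id"], ann["barcode"], ann["layer"])
    }

    sample_dirs = sorted(
        d for d in directory.iterdir() if d.is_dir() and (d / "matrix.mtx").exists()
    )
    if not sample_dirs:
        raise DatasetError(f"no sample subdirectories with matrix.mtx under {directory}")

    per_sample = []
    all_genes: set[str] = set()
    for sdir in sample_dirs:
        sample_id = sdir.name
        mtx = spio.mmread(_require(sdir / "matrix.mtx")).tocsc()
        genes = _read_features(_require(sdir / "features.tsv"))
        with open(_require(sdir / "barcodes.tsv")) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        if mtx.shape != (len(genes), len(barcodes)):
            raise DatasetError(
                f"{sample_id}: matrix shape {mtx.shape} does not match "
                f"{len(genes)} features x {len(barcodes)} barcodes"
            )
        pos = _read_positions(_require(sdir / "tissue_positions_list.csv"))
        pos = pos.set_index("barcode")
        missing_pos = [b for b in barcodes if b not in pos.index]
        if missing_pos:
            raise DatasetError(
                f"{sample_id}: barcodes missing from positions file: {missing_pos[:5]}"
            )
        all_genes.update(genes)
        per_sample.append((sample_id, mtx.T.tocsr(), genes, barcodes, pos))

    gene_union = pd.Index(sorted(all_genes))
    blocks = []
    spot_rows = []
    for sample_id, counts, genes, barcodes, pos in per_sample:
        # align this sample's genes into the union
        col_idx = gene_union.get_indexer(genes)
        mapped = sparse.csr_matrix(
            (counts.data, col_idx[counts.indices], counts.indptr),
            shape=(counts.shape[0], len(gene_union)),
        )
        order = np.argsort(np.array(barcodes, dtype=object), kind="stable")
        mapped = mapped[order]
        for bi in order:
            b = barcodes[bi]
            row = pos.loc[b]
            arow, acol = int(row["array_row"]), int(row["array_col"])
            if (arow + acol) % 2 != 0:
                raise DatasetError(
                    f"array parity violated for {sample_id}:{b} "
                    f"(array_row={arow}, array_col={acol})"
                )
            in_tissue = int(row["in_tissue"])
            layer = ann_map.get((sample_id, b))
            if layer is None:
                if in_tissue == 1:
                    raise DatasetError(
                        f"annotation missing for in-tissue spot {sample_id}:{b}"
                    )
                layer = "excluded"
            spot_rows.append((sample_id, b, in_tissue, arow, acol, layer))
        blocks.append(mapped)

    counts = sparse.vstack(blocks, format="csr") if blocks else sparse.csr_matrix((0, 0))
    spots = pd.DataFrame(spot_rows, columns=SPOT_COLUMNS)
    ds = SpotDataset(counts=counts.astype(np.int64), genes=gene_union, spots=spots, meta=meta)
    ds.validate()
    return ds


def save_dataset(ds: SpotDataset, directory: str | Path) -> None:
    """Write a dataset as the exact file set :func:`load_dataset` reads.

    Output is deterministic: genes and barcodes are written sorted, so two
    invocations on the same dataset produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    gene_order = np.argsort(ds.genes.values, kind="stable")
    genes_sorted = ds.genes[gene_order]

    meta = ds.meta.sort_index()
    meta.to_csv(directory / "metadata.csv", lineterminator="\n")

    ann = ds.spots.loc[
        ds.spots["in_tissue"] == 1, ["sample_id", "barcode", "layer"]
    ].sort_values(["sample_id", "barcode"], kind="stable")
    ann.to_csv(directory / "annotation.csv", index=False, lineterminator="\n")

    for sample_id in ds.sample_ids:
        smask = (ds.spots["sample_id"] == sample_id).to_numpy()
        sub = ds.spots.loc[smask].reset_index(drop=True)
        order = np.argsort(sub["barcode"].values, kind="stable")
        sub = sub.iloc[order]
        mat = ds.counts[smask][order][:, gene_order]

        sdir = directory / sample_id
        sdir.mkdir(exist_ok=True)
        spio.mmwrite(
            sdir / "matrix.mtx", sparse.coo_matrix(mat.T), field="integer"
        )
        with open(sdir / "features.tsv", "w") as fh:
            for g in genes_sorted:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(sdir / "barcodes.tsv", "w") as fh:
            for b in sub["barcode"]:
                fh.write(f"{b}\n")
        with open(sdir / "tissue_positions_list.csv", "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            for row in sub.itertuples(index=False):
                w.writerow(
                    [row.barcode, row.in_tissue, row.array_row, row.array_col, 0, 0]
                )


CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "sample_id",
    "radius",
    "n_seed_spots",
    "n_ring_spots",
    "cytokine_count",
    "responder_count",
    "weight",
]


def write_cluster_table(clusters: Sequence[DensityCluster], path: str | Path) -> None:
    """One CSV row per cluster, in the fixed column order
    ``cluster_id, sample_id, radius, n_seed_spots, n_ring_spots,
    cytokine_count, responder_count, weight``."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "sample_id": c.sample_id,
            "radius": c.radius,
            "n_seed_spots": c.n_seed_spots,
            "n_ring_spots": c.n_ring_spots,
            "cytokine_count": c.cytokine_count,
            "responder_count": c.responder_count,
            "weight": c.weight,
        }
        for c in clusters
    ]
    pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )
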