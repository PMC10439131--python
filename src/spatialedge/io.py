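"""Plain-text persistence: Matrix Market count layers + CSV metadata for
spatial samples, CSV drug and survival tables, JSON state graphs and
gene sets."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import DrugRecord
from .velocity import StateGraph

_LAYERS = ("spliced", "unspliced")


def write_sample(adata: ad.AnnData, outdir) -> Path:
    """Write one sample as MTX layers + TSV gene/barcode lists + a spot
    metadata CSV (obs columns, deconvolution proportions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(np.asarray(adata.X)))
    for layer in _LAYERS:
        if layer in adata.layers:
            spio.mmwrite(
                outdir / f"{layer}.mtx",
                sparse.csr_matrix(np.asarray(adata.layers[layer])),
            )
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = adata.obs.copy()
    if "deconv" in adata.obsm:
        deconv = adata.obsm["deconv"].add_prefix("deconv_")
        meta = pd.concat([meta, deconv], axis=1)
    meta.to_csv(outdir / "spots.csv")
    extras = {
        k: v
        for k, v in adata.uns.items()
        if k in ("gene_sets", "config", "sample_id")
    }
    if extras:
        (outdir / "uns.json").write_text(json.dumps(extras, default=_jsonify))
    return outdir


def read_sample(indir) -> ad.AnnData:
    """Read a sample written by :func:`write_sample`."""
    indir = Path(indir)
    X = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    meta = pd.read_csv(indir / "spots.csv", index_col=0)
    deconv_cols = [c for c in meta.columns if c.startswith("deconv_")]
    obs = meta.drop(columns=deconv_cols)
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if deconv_cols:
        adata.obsm["deconv"] = meta[deconv_cols].rename(
            columns=lambda c: c[len("deconv_"):]
        )
    for layer in _LAYERS:
        path = indir / f"{layer}.mtx"
        if path.exists():
            adata.layers[layer] = np.asarray(spio.mmread(path).todense()).astype(
                np.int64
            )
    uns_path = indir / "uns.json"
    if uns_path.exists():
        adata.uns.update(json.loads(uns_path.read_text()))
    return adata


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_state_graph(graph: StateGraph, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(graph.to_dict(), indent=2))
    return path


def read_state_graph(path) -> StateGraph:
    data = json.loads(Path(path).read_text())
    Q = pd.DataFrame(data["Q"], index=data["states"], columns=data["states"])
    return StateGraph(Q=Q)


def read_gene_sets(path) -> dict:
    """Gene sets from JSON ({name: [genes]} or {name: {up, down}}) or
    GMT (tab-separated: name, description, genes...)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = {}
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
        return sets
    return json.loads(path.read_text())


def drug_tables(records: list[DrugRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten drug records into the two standard CSV tables:
    (drug_id, cell_line, dataset, aac) and (drug_id, target_gene,
    keyword)."""
    aac = pd.concat(
        [r.aac.assign(drug_id=r.drug_id) for r in records], ignore_index=True
    )[["drug_id", "cell_line", "dataset", "aac"]]
    inter = pd.DataFrame(
        [
            (r.drug_id, gene, kw)
            for r in records
            for gene, kw in r.targets
        ],
        columns=["drug_id", "target_gene", "keyword"],
    )
    return aac, inter


def records_from_tables(
    aac: pd.DataFrame, interactions: pd.DataFrame, mechanisms: pd.DataFrame | None = None
) -> list[DrugRecord]:
    """Rebuild drug records from the standard CSV tables."""
    mech = (
        mechanisms.set_index("drug_id")["mechanism"].to_dict()
        if mechanisms is not None
        else {}
    )
    records = []
    for drug_id, sub in aac.groupby("drug_id", observed=True):
        targets = [
            (row.target_gene, row.keyword)
            for row in interactions[interactions["drug_id"] == drug_id].itertuples()
        ]
        records.append(
            DrugRecord(
                drug_id=str(drug_id),
                aac=sub[["cell_line", "dataset", "aac"]].reset_index(drop=True),
                targets=targets,
                mechanism=mech.get(drug_id),
            )
        )
    return records
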