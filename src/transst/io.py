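"""Readers, writers, gene alignment, preprocessing, and the PCA baseline.

File conventions
----------------
Dense layout: delimited text (TSV or CSV), spots in rows.  The header
row carries gene identifiers and the first column carries spot
identifiers.

Sparse layout: a MatrixMarket ``.mtx`` file with sidecar ``genes.tsv``
and ``barcodes.tsv`` files in the same directory (one identifier per
line).  By default the matrix is read as spots × genes; pass
``transpose=True`` for 10x-style genes × barcodes matrices.

Coordinates: two-column delimited text (x, y), optionally with a header
row, row-aligned with the target expression matrix.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

from .containers import Embedding, ExpressionMatrix, FactorModel, SpatialCoords, SpatialFit

__all__ = [
    "load_expression",
    "write_expression",
    "load_coords",
    "write_coords",
    "align_genes",
    "preprocess",
    "pca_embed",
    "save_factor_model",
    "load_factor_model",
    "save_spatial_fit",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene id(s) in {path}: {dup[:5]}")
    try:
        # round_trip parser: written values are recovered bitwise
        return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed expression file {path}: {exc}") from exc


def load_expression(path, layout: str = "dense", transpose: bool = False) -> ExpressionMatrix:
    """Load an expression matrix from disk.

    Parameters
    ----------
    path : str or Path
        Dense layout: the delimited text file.  Sparse layout: the
        ``.mtx`` file (sidecars ``genes.tsv``/``barcodes.tsv`` must sit
        next to it) or the directory containing ``matrix.mtx``.
    layout : {"dense", "sparse"}
    transpose : bool
        Sparse layout only: set True when the matrix stores genes in
        rows (10x convention).

    Returns
    -------
    ExpressionMatrix
        Spots in rows, genes in columns, input order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense":
        df = _read_table(path)
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric columns in {path}: {non_numeric[:5]}")
        return ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            gene_ids=df.columns.to_numpy(dtype=str),
            spot_ids=df.index.to_numpy(dtype=str),
        )
    if layout == "sparse":
        if path.is_dir():
            path = path / "matrix.mtx"
        mat = spio.mmread(path).toarray().astype(float)
        if transpose:
            mat = mat.T
        genes = _read_ids(path.parent / "genes.tsv")
        barcodes = _read_ids(path.parent / "barcodes.tsv")
        return ExpressionMatrix(values=mat, gene_ids=genes, spot_ids=barcodes)
    raise ValueError(f"unknown layout {layout!r}")


def _read_ids(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar id file {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    return np.asarray(ids, dtype=str)


def write_expression(expr: ExpressionMatrix, path, layout: str = "dense") -> None:
    """Write an expression matrix; dense round trips are bitwise exact."""
    path = Path(path)
    if layout == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(expr.values, index=expr.spot_ids, columns=expr.gene_ids)
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
        return
    if layout == "sparse":
        path.mkdir(parents=True, exist_ok=True)
        from scipy.sparse import coo_matrix

        spio.mmwrite(path / "matrix.mtx", coo_matrix(expr.values), precision=17)
        (path / "genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(expr.spot_ids) + "\n")
        return
    raise ValueError(f"unknown layout {layout!r}")


def load_coords(path) -> SpatialCoords:
    """Read two-column spot coordinates; a non-numeric first row is a header."""
    path = Path(path)
    first = path.open().readline()
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    has_header = not all(_is_number(tok) for tok in first.strip().split(sep))
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] != 2:
        raise ValueError(f"coordinate file must have exactly two columns, got {df.shape[1]}")
    return SpatialCoords(df.to_numpy(dtype=float))


def write_coords(coords: SpatialCoords, path) -> None:
    pd.DataFrame(coords.coords, columns=["x", "y"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def align_genes(source: ExpressionMatrix, target: ExpressionMatrix):
    """Restrict both matrices to their shared genes, in target gene order.

    Target genes absent from the source are dropped from both matrices
    (reported via a warning), because downstream spatial analysis is
    driven by the target panel.
    """
    src_pos = {g: j for j, g in enumerate(source.gene_ids)}
    shared = [g for g in target.gene_ids if g in src_pos]
    if not shared:
        raise ValueError("no genes shared between source and target")
    dropped_tgt = target.p - len(shared)
    dropped_src = source.p - len(shared)
    if dropped_tgt or dropped_src:
        warnings.warn(
            f"gene alignment dropped {dropped_tgt} target and {dropped_src} source genes; "
            f"{len(shared)} shared genes kept",
            stacklevel=2,
        )
    src_cols = np.array([src_pos[g] for g in shared])
    tgt_cols = np.array([list(target.gene_ids).index(g) for g in shared])
    src_out = ExpressionMatrix(source.values[:, src_cols], np.array(shared), source.spot_ids)
    tgt_out = ExpressionMatrix(target.values[:, tgt_cols], np.array(shared), target.spot_ids)
    return src_out, tgt_out


def preprocess(
    expr: ExpressionMatrix,
    n_hvg: int,
    do_scale: bool = True,
    already_normalized: bool = False,
) -> ExpressionMatrix:
    """Standard expression preprocessing.

    Raw counts go through library-size normalization to the median
    depth followed by log1p; matrices declared ``already_normalized``
    skip both.  The top ``n_hvg`` genes by variance of the (log)
    values are kept, ties broken by ascending gene index, and genes are
    optionally centered and scaled to unit variance.  Deterministic.
    """
    if n_hvg > expr.p:
        raise ValueError(f"n_hvg={n_hvg} exceeds number of genes p={expr.p}")
    if n_hvg < 1:
        raise ValueError("n_hvg must be positive")
    values = expr.values
    spot_ids = expr.spot_ids
    if not already_normalized:
        if np.any(values < 0):
            raise ValueError("raw counts must be nonnegative; pass already_normalized=True "
                             "for normalized data")
        depth = values.sum(axis=1)
        keep = depth > 0
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} all-zero spots", stacklevel=2)
            values = values[keep]
            spot_ids = spot_ids[keep]
            depth = depth[keep]
            if values.shape[0] == 0:
                raise ValueError("all spots were empty")
        values = np.log1p(values * (np.median(depth) / depth)[:, None])
    var = values.var(axis=0)
    # descending variance, ascending gene index on ties
    order = np.lexsort((np.arange(values.shape[1]), -var))
    keep_cols = np.sort(order[:n_hvg])
    values = values[:, keep_cols]
    gene_ids = expr.gene_ids[keep_cols]
    if do_scale:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    return ExpressionMatrix(values, gene_ids, spot_ids)


def pca_embed(expr: ExpressionMatrix, q: int) -> Embedding:
    """Top-q principal component scores of the column-centered matrix.

    The sign of each component is fixed so that its largest-magnitude
    loading entry is positive.
    """
    scores, _ = pca_scores_loadings(np.asarray(expr.values, dtype=float), q)
    return Embedding(scores)


def pca_scores_loadings(X: np.ndarray, q: int):
    """Sign-fixed PCA scores (n×q) and loadings (p×q) of centered ``X``."""
    n, p = X.shape
    if q < 1 or q > min(n, p):
        raise ValueError(f"q={q} must lie in [1, min(n,p)={min(n, p)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[q - 1] <= s[0] * 1e-12:
        raise ValueError(f"q={q} exceeds the numerical rank of the matrix")
    comps = Vt[:q]
    flip = np.sign(comps[np.arange(q), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    scores = U[:, :q] * s[:q] * flip
    return scores, comps.T


# ---------------------------------------------------------------------------
# fit serialization: directories of TSVs plus a JSON manifest


def save_factor_model(model: FactorModel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "loading.tsv", model.loading, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(outdir / "resid_var.tsv", model.resid_var, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(outdir / "cluster_means.tsv", model.cluster_means, delimiter="\t", fmt=_FLOAT_FMT)
    meta = {
        "cluster_covs": model.cluster_covs.tolist(),
        "loglik_trace": list(map(float, model.loglik_trace)),
    }
    (outdir / "factor_model.json").write_text(json.dumps(meta))


def load_factor_model(outdir) -> FactorModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "factor_model.json").read_text())
    return FactorModel(
        loading=np.loadtxt(outdir / "loading.tsv", delimiter="\t", ndmin=2),
        resid_var=np.loadtxt(outdir / "resid_var.tsv", delimiter="\t", ndmin=1),
        cluster_means=np.loadtxt(outdir / "cluster_means.tsv", delimiter="\t", ndmin=2),
        cluster_covs=np.asarray(meta["cluster_covs"], dtype=float),
        loglik_trace=meta["loglik_trace"],
    )


def save_spatial_fit(fit: SpatialFit, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "labels.tsv", fit.labels, fmt="%d")
    np.savetxt(outdir / "responsibilities.tsv", fit.responsibilities,
               delimiter="\t", fmt=_FLOAT_FMT)
    params = {
        "beta": fit.beta,
        "K": fit.K,
        "weights": np.asarray(fit.weights).tolist(),
        "criterion_value": fit.criterion_value,
        "pseudo_loglik": fit.pseudo_loglik,
        "pseudo_loglik_trace": list(map(float, fit.pseudo_loglik_trace)),
        "cluster_means": fit.cluster_means.tolist(),
        "cluster_covs": fit.cluster_covs.tolist(),
        "criterion_table": {str(k): v for k, v in fit.criterion_table.items()},
    }
    (outdir / "spatial_fit.json").write_text(json.dumps(params))


def write_manifest(manifest: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
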