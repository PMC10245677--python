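"""Empty-droplet diagnostics for nascent/mature UMI count matrices.

Under the pseudobulk background model, empty droplets should show
(i) Poisson per-gene mean-variance (log-log slope 1, intercept 0),
(ii) near-zero intra-gene nascent-mature Pearson correlation,
(iii) near-zero inter-gene correlations, and
(iv) empty-droplet means proportional to cell-droplet means.
Cell-containing droplets violate all four.  Statistics are computed on raw
counts (the predictions concern raw-count independence); undefined
correlations (zero-variance genes) are omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "QCReport",
    "load_counts",
    "save_counts",
    "mean_variance_table",
    "correlation_screens",
    "overdispersion_screen",
    "total_count_fano",
    "empty_vs_cell_means",
    "qc_report",
]


@dataclass
class QCReport:
    mean_variance: dict
    intra_gene_rho: np.ndarray
    inter_gene_rho: dict
    flagged_genes: np.ndarray
    fano_all: float
    fano_excluding_flagged: float
    empty_vs_cell: dict
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        payload = {
            "mean_variance": _clean(self.mean_variance),
            "intra_gene_rho": _clean(self.intra_gene_rho),
            "inter_gene_rho": _clean(self.inter_gene_rho),
            "flagged_genes": _clean(self.flagged_genes),
            "fano_all": self.fano_all,
            "fano_excluding_flagged": self.fano_excluding_flagged,
            "empty_vs_cell": _clean(self.empty_vs_cell),
            "meta": _clean(self.meta),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_counts(
    nascent_mtx: str | Path,
    mature_mtx: str | Path,
    barcodes_tsv: str | Path,
    genes_tsv: str | Path,
    labels_tsv: str | Path | None = None,
):
    """Load aligned nascent/mature matrices (droplets x genes) from MTX + TSV.

    Returns ``(nascent, mature, barcodes, genes, is_cell)``; ``is_cell`` is
    None when no label file is given.
    """
    for p in (nascent_mtx, mature_mtx, barcodes_tsv, genes_tsv):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    nasc = np.asarray(mmread(str(nascent_mtx)).todense())
    mat = np.asarray(mmread(str(mature_mtx)).todense())
    barcodes = pd.read_csv(barcodes_tsv, sep="\t", header=None)[0].tolist()
    genes = pd.read_csv(genes_tsv, sep="\t", header=None)[0].tolist()
    if nasc.shape != mat.shape:
        raise ValueError(f"nascent {nasc.shape} and mature {mat.shape} shapes differ")
    if nasc.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {nasc.shape} does not match {len(barcodes)} barcodes "
            f"x {len(genes)} genes"
        )
    is_cell = None
    if labels_tsv is not None:
        is_cell = pd.read_csv(labels_tsv, sep="\t", header=None)[0].astype(bool).to_numpy()
        if len(is_cell) != len(barcodes):
            raise ValueError("label vector length does not match barcodes")
    return nasc, mat, barcodes, genes, is_cell


def save_counts(dataset, outdir: str | Path) -> None:
    """Write a DropletDataset as MTX (per species) + barcodes/genes/labels TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "nascent.mtx"), coo_matrix(dataset.nascent))
    mmwrite(str(outdir / "mature.mtx"), coo_matrix(dataset.mature))
    pd.Series(dataset.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    pd.Series(dataset.gene_names).to_csv(outdir / "genes.tsv", sep="\t",
                                         header=False, index=False)
    pd.Series(dataset.is_cell.astype(int)).to_csv(outdir / "labels.tsv", sep="\t",
                                                  header=False, index=False)
    (outdir / "metadata.json").write_text(json.dumps(dataset.metadata, indent=1))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mean_variance_table(matrix: np.ndarray) -> pd.DataFrame:
    """Per-gene sample mean and variance, with log-log columns where defined."""
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValueError("empty count matrix")
    mu = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    df = pd.DataFrame({"mean": mu, "variance": var})
    ok = (mu > 0) & (var > 0)
    df["log_mean"] = np.where(ok, np.log10(np.maximum(mu, 1e-300)), np.nan)
    df["log_variance"] = np.where(ok, np.log10(np.maximum(var, 1e-300)), np.nan)
    return df


def loglog_slope(df: pd.DataFrame) -> tuple[float, float]:
    """OLS slope/intercept of log variance vs log mean (defined pairs only)."""
    sub = df.dropna(subset=["log_mean", "log_variance"])
    if len(sub) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(sub["log_mean"], sub["log_variance"], 1)
    return float(slope), float(intercept)


def correlation_screens(nascent: np.ndarray, mature: np.ndarray,
                        max_pairs: int = 200_000, seed: int = 0):
    """Intra-gene (nascent vs mature) and inter-gene Pearson correlations.

    Undefined correlations (zero variance) are omitted; the inter-gene screen
    is restricted to expressed genes (nonzero total count) and subsampled to
    at most ``max_pairs`` gene pairs.
    """
    nascent = np.asarray(nascent, dtype=float)
    mature = np.asarray(mature, dtype=float)
    n_drop, n_gene = nascent.shape
    intra = []
    if n_drop >= 2:
        for j in range(n_gene):
            a, b = nascent[:, j], mature[:, j]
            if a.std() == 0 or b.std() == 0:
                continue
            intra.append(float(np.corrcoef(a, b)[0, 1]))
    intra = np.asarray(intra)

    inter = {}
    for name, matx in (("nascent", nascent), ("mature", mature)):
        expressed = np.where(matx.sum(axis=0) > 0)[0]
        vals = []
        if n_drop >= 2 and len(expressed) >= 2:
            sub = matx[:, expressed]
            sd = sub.std(axis=0)
            keep = sd > 0
            sub = sub[:, keep]
            if sub.shape[1] >= 2:
                Cm = np.corrcoef(sub.T)
                iu = np.triu_indices(Cm.shape[0], k=1)
                vals = Cm[iu]
                if len(vals) > max_pairs:
                    rng = np.random.default_rng(seed)
                    vals = rng.choice(vals, size=max_pairs, replace=False)
        inter[name] = np.asarray(vals)
    return intra, inter


def overdispersion_screen(matrix: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Indices of genes with sample variance > factor * mean (default 2x)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0 or matrix.shape[0] < 2:
        return np.array([], dtype=int)
    mu = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1)
    return np.where(var > factor * mu)[0]


def total_count_fano(matrix: np.ndarray, exclude: np.ndarray | None = None) -> float:
    """Fano factor (variance/mean) of per-droplet total counts."""
    matrix = np.asarray(matrix, dtype=float)
    if exclude is not None and len(exclude):
        keep = np.setdiff1d(np.arange(matrix.shape[1]), np.asarray(exclude))
        matrix = matrix[:, keep]
    totals = matrix.sum(axis=1)
    if len(totals) < 2 or totals.mean() == 0:
        return float("nan")
    return float(totals.var(ddof=1) / totals.mean())


def empty_vs_cell_means(matrix: np.ndarray, is_cell: np.ndarray) -> dict:
    """Log-log regression of empty-droplet gene means on cell-droplet means."""
    matrix = np.asarray(matrix, dtype=float)
    is_cell = np.asarray(is_cell, dtype=bool)
    mu_cell = matrix[is_cell].mean(axis=0)
    mu_empty = matrix[~is_cell].mean(axis=0)
    ok = (mu_cell > 0) & (mu_empty > 0)
    if ok.sum() < 2:
        return {"slope": float("nan"), "intercept": float("nan"),
                "pearson_r": float("nan"), "n": int(ok.sum())}
    lx, ly = np.log10(mu_cell[ok]), np.log10(mu_empty[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    r = float(np.corrcoef(lx, ly)[0, 1])
    return {"slope": float(slope), "intercept": float(intercept),
            "pearson_r": r, "n": int(ok.sum())}


def qc_report(nascent: np.ndarray, mature: np.ndarray,
              is_cell: np.ndarray) -> QCReport:
    """Full empty-droplet QC: all four pseudobulk predictions on one dataset."""
    is_cell = np.asarray(is_cell, dtype=bool)
    empties_n, empties_m = nascent[~is_cell], mature[~is_cell]
    mv_n = mean_variance_table(empties_n)
    mv_m = mean_variance_table(empties_m)
    slope_n, icpt_n = loglog_slope(mv_n)
    slope_m, icpt_m = loglog_slope(mv_m)
    intra, inter = correlation_screens(empties_n, empties_m)
    flagged = overdispersion_screen(empties_m)
    fano_all = total_count_fano(empties_m)
    fano_ex = total_count_fano(empties_m, exclude=flagged)
    evc = empty_vs_cell_means(mature, is_cell)
    return QCReport(
        mean_variance={
            "nascent": {"slope": slope_n, "intercept": icpt_n},
            "mature": {"slope": slope_m, "intercept": icpt_m},
        },
        intra_gene_rho=intra,
        inter_gene_rho={k: v for k, v in inter.items()},
        flagged_genes=flagged,
        fano_all=fano_all,
        fano_excluding_flagged=fano_ex,
        empty_vs_cell=evc,
        meta={"n_droplets": int(nascent.shape[0]),
              "n_empty": int((~is_cell).sum()),
              "n_genes": int(nascent.shape[1])},
    )
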