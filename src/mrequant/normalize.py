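"""Library-size / UTR-length / GC normalization of raw MRE counts.

Raw counts are first put on an RPKM-like log2 scale,

    y_pre = log2(c + pseudocount) - log2(N_s / 1e6) - log2(L_g / 1e3),

then a per-sample GC-content effect is removed by a binned-median offset
model: MRE rows are binned by their gene's GC fraction, the per-sample bin
median is shifted onto the across-sample grand bin median, and the offset is
interpolated linearly between bin centers (constant beyond the outer
centers). This is a deterministic, dependency-free stand-in for
conditional-quantile-style GC correction: it removes the same systematic
per-sample GC trend while preserving within-bin ranks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import MRECountMatrix

logger = logging.getLogger(__name__)


def base_normalize(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    gene_lengths: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """RPKM-like log2 values: library-size and UTR-length adjusted counts.

    ``counts`` rows are (gene_id, family_id); ``gene_lengths`` maps gene_id
    to 3'UTR length in nt. Samples with N_s = 0 are rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lib = lib_sizes.reindex(counts.columns)
    if lib.isna().any():
        raise ValueError(f"missing library sizes for {list(lib[lib.isna()].index)}")
    if (lib <= 0).any():
        bad = list(lib[lib <= 0].index)
        raise ValueError(f"samples with zero library size: {bad}")
    genes = counts.index.get_level_values("gene_id")
    L = gene_lengths.reindex(genes)
    if L.isna().any():
        missing = sorted(set(genes[L.isna().to_numpy()]))
        raise ValueError(f"missing UTR lengths for genes: {missing[:10]}")
    if (L <= 0).any():
        raise ValueError("non-positive UTR length")
    y = np.log2(counts.to_numpy(dtype=float) + pseudocount)
    y -= np.log2(lib.to_numpy(dtype=float) / 1e6)[None, :]
    y -= np.log2(L.to_numpy(dtype=float) / 1e3)[:, None]
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


@dataclass
class NormalizationModel:
    """Fitted binned-median GC-offset model.

    ``bin_edges`` partition [0, 1]; ``m`` holds per-sample bin medians of
    y_pre (samples x bins) and ``m_bar`` the across-sample median per bin.
    The per-sample correction at GC value g is the linear interpolation of
    ``m[s] - m_bar`` between bin centers.
    """

    pseudocount: float
    bin_edges: np.ndarray
    sample_ids: list[str]
    m: np.ndarray       # (n_samples, n_bins)
    m_bar: np.ndarray   # (n_bins,)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def offsets(self, sample_id: str, gc: np.ndarray) -> np.ndarray:
        """delta_s(gc): interpolated per-sample offset, constant beyond outer centers."""
        gc = np.asarray(gc, dtype=float)
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc values outside [0, 1]")
        s = self.sample_ids.index(sample_id)
        delta = self.m[s] - self.m_bar
        return np.interp(gc, self.bin_centers, delta)

    def assign_bins(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        idx = np.searchsorted(self.bin_edges, gc, side="right") - 1
        return np.clip(idx, 0, len(self.bin_edges) - 2)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "pseudocount": self.pseudocount,
            "bin_edges": self.bin_edges.tolist(),
            "sample_ids": self.sample_ids,
            "m": self.m.tolist(),
            "m_bar": self.m_bar.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            pseudocount=obj["pseudocount"],
            bin_edges=np.array(obj["bin_edges"]),
            sample_ids=list(obj["sample_ids"]),
            m=np.array(obj["m"]),
            m_bar=np.array(obj["m_bar"]),
        )


def _merged_edges(gc: np.ndarray, n_bins: int, min_sites: int) -> np.ndarray:
    """Equal-width bins on [0,1]; bins with < min_sites rows merged into a neighbor."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
        occ = np.bincount(idx, minlength=len(edges) - 1)
        small = np.flatnonzero(occ < min_sites)
        if small.size == 0:
            break
        b = small[0]
        # merge with the smaller neighbor (leftmost tie-break)
        if b == 0:
            drop = 1
        elif b == len(occ) - 1:
            drop = b
        else:
            drop = b if occ[b - 1] <= occ[b + 1] else b + 1
        edges = np.delete(edges, drop)
    return edges


def fit_gc_correction(
    y_pre: pd.DataFrame,
    gc_by_gene: pd.Series,
    n_bins: int = 20,
    min_sites: int = 50,
    pseudocount: float = 0.5,
) -> NormalizationModel:
    """Fit the per-sample binned-median GC-offset model.

    Each MRE row takes its gene's GC fraction gc_g. Requires >= 2 samples;
    a sample with all-identical values gets zero offsets (warned).
    """
    if y_pre.shape[1] < 2:
        raise ValueError("fit_gc_correction requires at least 2 samples")
    gc = gc_by_gene.reindex(y_pre.index.get_level_values("gene_id")).to_numpy(dtype=float)
    if np.isnan(gc).any():
        raise ValueError("missing GC values for some genes")
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc values outside [0, 1]")
    edges = _merged_edges(gc, n_bins, min_sites)
    idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    n_b = len(edges) - 1
    vals = y_pre.to_numpy(dtype=float)
    m = np.empty((y_pre.shape[1], n_b))
    for b in range(n_b):
        rows = idx == b
        if rows.any():
            m[:, b] = np.median(vals[rows, :], axis=0)
        else:  # merged bins make this rare; fall back to the global median
            m[:, b] = np.median(vals, axis=0)
    m_bar = np.median(m, axis=0)
    for s, sample in enumerate(y_pre.columns):
        if np.ptp(vals[:, s]) == 0:
            warnings.warn(f"sample {sample}: all values identical; zero GC offsets")
            m[s] = m_bar
    return NormalizationModel(
        pseudocount=pseudocount,
        bin_edges=edges,
        sample_ids=list(y_pre.columns),
        m=m,
        m_bar=m_bar,
    )


def apply_gc_correction(
    y_pre: pd.DataFrame, gc_by_gene: pd.Series, model: NormalizationModel
) -> pd.DataFrame:
    """y = y_pre - delta_s(gc_g); finite for all entries."""
    gc = gc_by_gene.reindex(y_pre.index.get_level_values("gene_id")).to_numpy(dtype=float)
    out = y_pre.copy().astype(float)
    for sample in y_pre.columns:
        out[sample] = y_pre[sample].to_numpy() - model.offsets(sample, gc)
    return out


def normalize_counts(
    matrix: MRECountMatrix,
    gene_table: pd.DataFrame,
    pseudocount: float = 0.5,
    n_bins: int = 20,
    min_sites: int = 50,
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Full normalization: base RPKM-like log2 values plus GC-offset correction.

    ``gene_table`` carries per-gene ``length`` and ``gc`` columns (the 3'UTR
    covariates). Returns (normalized matrix, fitted model).
    """
    y_pre = base_normalize(
        matrix.counts, matrix.library_sizes(), gene_table["length"], pseudocount
    )
    model = fit_gc_correction(
        y_pre, gene_table["gc"], n_bins=n_bins, min_sites=min_sites, pseudocount=pseudocount
    )
    y = apply_gc_correction(y_pre, gene_table["gc"], model)
    return y, model
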