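"""LD scores, band r² matrices, 1 cM blocks and working correlations.

All quantities derive from a panel of phased reference haplotypes together
with a genetic map.  LD between two variants is the squared Pearson
correlation r² of their haplotype allele indicators; LD is treated as zero
beyond a genetic-distance cutoff (1 cM by default), which induces a band
structure.  The genome is partitioned into consecutive 1 cM blocks whose
principal r² submatrices, after a positive-semidefinite repair, serve as
GEE working-correlation matrices for the squared association statistics.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMapTrack",
    "BandLDMatrix",
    "LDBlock",
    "ld_scores",
    "band_ld_matrix",
    "partition_blocks",
    "working_correlations",
    "shrink_correlation",
    "adjacency",
    "psd_repair",
    "polymorphic_mask",
    "read_genetic_map",
    "read_ldscores",
    "write_ldscores",
    "read_haplotypes_txt",
    "read_vcf_haplotypes",
]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMapTrack:
    """Genetic positions (cM) keyed by (chromosome, bp).

    Positions are 1-based bp (VCF convention); cM must be nondecreasing in
    bp within each chromosome.  Interpolation is linear in bp between
    flanking map points and returns NaN outside the map's span.
    """

    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            b, g = self.bp[sel], self.cm[sel]
            order = np.argsort(b)
            if np.any(np.diff(g[order]) < 0):
                raise ValueError(f"cM positions decrease with bp on chromosome {c}")

    def interpolate(self, chrom: Sequence, bp: Sequence[int]) -> np.ndarray:
        """cM positions for query variants; NaN outside the mapped span."""
        chrom = np.asarray(chrom)
        bp = np.asarray(bp, dtype=float)
        out = np.full(bp.shape, np.nan)
        for c in np.unique(chrom):
            sel_map = self.chrom == c
            if not sel_map.any():
                continue
            b, g = self.bp[sel_map].astype(float), self.cm[sel_map]
            order = np.argsort(b)
            b, g = b[order], g[order]
            sel_q = chrom == c
            q = bp[sel_q]
            vals = np.interp(q, b, g)
            vals[(q < b[0]) | (q > b[-1])] = np.nan
            out[sel_q] = vals
        return out


def read_genetic_map(path: str | Path) -> GeneticMapTrack:
    """Read a genetic map: 3 columns (chr, bp, cM) or PLINK .map (chr, id, cM, bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)

    def _numeric(x: str) -> bool:
        try:
            float(x)
            return True
        except ValueError:
            return False

    # header iff the trailing (position) fields of the first row are not numeric
    if not all(_numeric(v) for v in df.iloc[0, -2:]):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 4:  # PLINK .map: chr, snp, cM, bp
        chrom, cm, bp = df[0], df[2].astype(float), df[3].astype(int)
    elif df.shape[1] == 3:
        chrom, bp, cm = df[0], df[1].astype(int), df[2].astype(float)
    else:
        raise ValueError(f"unrecognized genetic map layout with {df.shape[1]} columns")
    return GeneticMapTrack(
        chrom=chrom.to_numpy(dtype=object), bp=bp.to_numpy(), cm=cm.to_numpy()
    )


# ---------------------------------------------------------------------------
# LD computation
# ---------------------------------------------------------------------------


def polymorphic_mask(haplotypes: np.ndarray, maf_min: float = 1e-6) -> np.ndarray:
    """Mask of variants with minor-allele frequency >= ``maf_min`` in the panel.

    r² is undefined for monomorphic columns; callers drop them (with a
    warning) before any LD computation.
    """
    freq = np.asarray(haplotypes, dtype=float).mean(axis=0)
    mask = np.minimum(freq, 1.0 - freq) >= maf_min
    if not mask.all():
        logger.warning(
            "excluding %d monomorphic/near-monomorphic variants from LD computation",
            int((~mask).sum()),
        )
    return mask


def _standardize(haplotypes: np.ndarray) -> np.ndarray:
    H = np.asarray(haplotypes, dtype=float)
    sd = H.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            "monomorphic variants present; drop them first (see polymorphic_mask)"
        )
    return (H - H.mean(axis=0)) / sd


def _window_bounds(cm: np.ndarray, window_cm: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(cm, cm - window_cm, side="left")
    hi = np.searchsorted(cm, cm + window_cm, side="right")
    return lo, hi


def _check_sorted(cm: np.ndarray, chrom: np.ndarray | None) -> list[tuple[object, np.ndarray]]:
    """Split indices by chromosome, verifying cM are sorted within each."""
    n = len(cm)
    if chrom is None:
        chrom = np.zeros(n, dtype=object)
    chrom = np.asarray(chrom)
    groups = []
    seen = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if np.any(np.diff(idx) != 1):
            raise ValueError("variants of one chromosome must be contiguous")
        if np.any(np.diff(cm[idx]) < 0):
            raise ValueError(f"variants not sorted by genetic position on {c}")
        seen.append(c)
        groups.append((c, idx))
    return groups


def ld_scores(
    haplotypes: np.ndarray,
    cm: np.ndarray,
    chrom: np.ndarray | None = None,
    window_cm: float = 1.0,
) -> np.ndarray:
    """Windowed LD scores ``l_l = sum_v r^2_{lv}`` over ``|cM_v - cM_l| <= window``.

    The sum includes ``v = l``, so every score is >= 1.  ``haplotypes`` is a
    (n_haplotypes, n_variants) 0/1 matrix of phased alleles ordered by
    position.
    """
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    Z = _standardize(haplotypes)
    n_hap = Z.shape[0]
    cm = np.asarray(cm, dtype=float)
    out = np.empty(Z.shape[1])
    for _, idx in _check_sorted(cm, chrom):
        sub_cm = cm[idx]
        lo, hi = _window_bounds(sub_cm, window_cm)
        Zc = Z[:, idx]
        for j in range(len(idx)):
            r = Zc[:, j] @ Zc[:, lo[j] : hi[j]] / n_hap
            out[idx[j]] = np.sum(r * r)
    return out


@dataclass
class BandLDMatrix:
    """Symmetric sparse r² matrix over ordered variants, zero beyond a cM cutoff."""

    r2: sparse.csr_matrix
    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray
    cutoff_cm: float

    @property
    def n_variants(self) -> int:
        return self.r2.shape[0]

    def scores(self) -> np.ndarray:
        """LD scores over this variant set (row sums of r²)."""
        return np.asarray(self.r2.sum(axis=1)).ravel()

    def block(self, start: int, stop: int) -> np.ndarray:
        """Dense principal submatrix for variants [start, stop)."""
        return self.r2[start:stop, start:stop].toarray()

    def submatrix(self, indices: np.ndarray) -> "BandLDMatrix":
        indices = np.asarray(indices)
        if np.any(np.diff(indices) < 0):
            raise ValueError("indices must be sorted")
        return BandLDMatrix(
            r2=self.r2[indices][:, indices].tocsr(),
            chrom=self.chrom[indices],
            bp=self.bp[indices],
            cm=self.cm[indices],
            cutoff_cm=self.cutoff_cm,
        )

    # -- persistence: gzip triplets + JSON sidecar -------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        coo = sparse.triu(self.r2).tocoo()
        with gzip.open(prefix.with_suffix(".ldm.gz"), "wt") as fh:
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")
        variants = [f"{c}:{b}" for c, b in zip(self.chrom, self.bp)]
        sidecar = {
            "cutoff_cm": self.cutoff_cm,
            "n_variants": self.n_variants,
            "chrom": [str(c) for c in self.chrom],
            "bp": [int(b) for b in self.bp],
            "cm": [float(g) for g in self.cm],
            "variant_hash": hashlib.sha1("\n".join(variants).encode()).hexdigest(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "BandLDMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        n = meta["n_variants"]
        rows, cols, vals = [], [], []
        with gzip.open(prefix.with_suffix(".ldm.gz"), "rt") as fh:
            for line in fh:
                i, j, v = line.split()
                rows.append(int(i))
                cols.append(int(j))
                vals.append(float(v))
        upper = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        full = upper + upper.T - sparse.diags(upper.diagonal())
        return cls(
            r2=full.tocsr(),
            chrom=np.array(meta["chrom"], dtype=object),
            bp=np.array(meta["bp"], dtype=int),
            cm=np.array(meta["cm"], dtype=float),
            cutoff_cm=float(meta["cutoff_cm"]),
        )


def band_ld_matrix(
    haplotypes: np.ndarray,
    cm: np.ndarray,
    chrom: np.ndarray | None = None,
    bp: np.ndarray | None = None,
    cutoff_cm: float = 1.0,
) -> BandLDMatrix:
    """Band r² matrix: squared haplotype correlation within ``cutoff_cm``, zero outside."""
    if cutoff_cm <= 0:
        raise ValueError("cutoff_cm must be positive")
    Z = _standardize(haplotypes)
    n_hap, n_var = Z.shape
    cm = np.asarray(cm, dtype=float)
    if chrom is None:
        chrom_arr = np.zeros(n_var, dtype=object)
    else:
        chrom_arr = np.asarray(chrom, dtype=object)
    if bp is None:
        bp = np.round(cm * 1e6).astype(int)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for _, idx in _check_sorted(cm, chrom_arr):
        sub_cm = cm[idx]
        _, hi = _window_bounds(sub_cm, cutoff_cm)
        Zc = Z[:, idx]
        for j in range(len(idx)):
            cols_j = np.arange(j, hi[j])
            r = Zc[:, j] @ Zc[:, j : hi[j]] / n_hap
            rows.append(idx[np.full(len(cols_j), j)])
            cols.append(idx[cols_j])
            vals.append(r * r)
    upper = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_var, n_var),
    ).tocsr()
    full = upper + upper.T - sparse.diags(upper.diagonal())
    return BandLDMatrix(
        r2=full.tocsr(),
        chrom=chrom_arr,
        bp=np.asarray(bp, dtype=int),
        cm=cm,
        cutoff_cm=cutoff_cm,
    )


# ---------------------------------------------------------------------------
# blocks and working correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDBlock:
    """A 1 cM cluster: contiguous variant range [start, stop) on one chromosome."""

    index: int
    chrom: object
    start: int
    stop: int
    cm_start: float
    cm_end: float

    @property
    def size(self) -> int:
        return self.stop - self.start


def partition_blocks(
    cm: np.ndarray, chrom: np.ndarray | None = None, block_cm: float = 1.0
) -> list[LDBlock]:
    """Partition variants into consecutive half-open ``block_cm`` intervals.

    Intervals are ``[k*block_cm, (k+1)*block_cm)`` per chromosome, anchored
    at the chromosome's map origin (cM coordinate zero); empty intervals are
    dropped.  Variants must be sorted by (chromosome, cM).
    """
    if block_cm <= 0:
        raise ValueError("block_cm must be positive")
    cm = np.asarray(cm, dtype=float)
    blocks: list[LDBlock] = []
    for c, idx in _check_sorted(cm, chrom):
        keys = np.floor(cm[idx] / block_cm).astype(int)
        change = np.flatnonzero(np.diff(keys)) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(idx)]])
        for s, e in zip(starts, stops):
            k = keys[s]
            blocks.append(
                LDBlock(
                    index=len(blocks),
                    chrom=c,
                    start=int(idx[s]),
                    stop=int(idx[e - 1]) + 1,
                    cm_start=k * block_cm,
                    cm_end=(k + 1) * block_cm,
                )
            )
    return blocks


def psd_repair(R: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal.

    Band truncation (and shrinkage of r to r²) can make a correlation
    submatrix indefinite; the repaired matrix is the eigenvalue-clipped
    version renormalized back to a correlation matrix, hence symmetric
    positive definite.  The floor also bounds the condition number of the
    working matrices (roughly m/floor): near-null directions of a panel
    r² matrix are estimation noise, and letting them into V^{-1} puts
    enormous weight on contrasts the data cannot inform, which destabilizes
    the estimating equations.
    """
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w[0] >= floor:
        return R
    A = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return 0.5 * (A + A.T)


def working_correlations(
    ld: BandLDMatrix, blocks: Iterable[LDBlock], psd_floor: float = 1e-3
) -> list[np.ndarray]:
    """Working-correlation matrices: per-block r² submatrices, PSD-repaired."""
    out = []
    for b in blocks:
        R = ld.block(b.start, b.stop)
        np.fill_diagonal(R, 1.0)
        out.append(psd_repair(R, floor=psd_floor))
    return out


def shrink_correlation(R: np.ndarray, factor: float) -> np.ndarray:
    """Shrink towards the identity: ``R' = s R + (1 - s) I`` for s in [0, 1]."""
    if not 0.0 <= factor <= 1.0:
        raise ValueError("shrink factor must lie in [0, 1]")
    n = R.shape[0]
    return factor * R + (1.0 - factor) * np.eye(n)


def adjacency(blocks: Sequence[LDBlock]) -> frozenset[tuple[int, int]]:
    """Pairs of clusters treated as correlated: consecutive blocks on one chromosome.

    With generation LD truncated at 1 cM and blocks of 1 cM, only adjacent
    blocks can share correlated statistics; these pairs enter the sandwich
    cross-term.
    """
    pairs = set()
    for a, b in zip(blocks, blocks[1:]):
        if a.chrom == b.chrom:
            pairs.add((a.index, b.index))
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_ldscores(path: str | Path) -> pd.DataFrame:
    """Read an LD-score table (tab-separated, columns CHR, SNP, BP, L2)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = {"CHR", "SNP", "BP", "L2"} - set(df.columns)
    if missing:
        raise ValueError(f"LD-score file missing columns: {sorted(missing)}")
    return df


def write_ldscores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["CHR", "SNP", "BP", "L2"])


def read_haplotypes_txt(path: str | Path) -> np.ndarray:
    """Read a plain 0/1 haplotype matrix (rows = haplotypes, columns = variants)."""
    H = np.loadtxt(path, dtype=np.int8, comments="#")
    H = np.atleast_2d(H)
    if not np.isin(H, (0, 1)).all():
        raise ValueError("haplotype matrix must be 0/1")
    return H


def read_vcf_haplotypes(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phased haplotypes from a VCF.

    Returns ``(haplotypes, chrom, bp, ref, alt)`` with haplotypes of shape
    (2 * n_samples, n_variants).  Only phased, biallelic sites with complete
    genotypes are kept; others are skipped with a warning.
    """
    from cyvcf2 import VCF  # deferred: heavy import

    haps, chroms, bps, refs, alts = [], [], [], [], []
    skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = np.array(var.genotypes)  # (n_samples, 3): a0, a1, phased
        if gts.shape[1] < 3 or not gts[:, 2].all() or (gts[:, :2] < 0).any():
            skipped += 1
            continue
        haps.append(gts[:, :2].reshape(-1).astype(np.int8))
        chroms.append(var.CHROM)
        bps.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if skipped:
        logger.warning("skipped %d unphased/multiallelic/incomplete VCF records", skipped)
    if not haps:
        raise ValueError(f"no usable phased biallelic records in {path}")
    return (
        np.column_stack(haps),
        np.array(chroms, dtype=object),
        np.array(bps, dtype=int),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
    )
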