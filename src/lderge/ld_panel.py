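"""Block-wise LD reference panels: build, shrink, partition, eigen-decompose, serialize.

The estimator consumes LD information as per-block eigen systems of the variant
correlation matrix R.  A panel is a list of :class:`EigenSystem` objects plus the
variant metadata, built either from a reference genotype matrix or loaded from a
serialized archive.  Blocks are quasi-independent genomic segments: no strongly
linked variant pair may span a block boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VariantInfo",
    "LDBlock",
    "EigenSystem",
    "compute_ld_matrix",
    "shrink_ld",
    "ledoit_wolf_intensity",
    "partition_blocks",
    "eigendecompose_block",
    "build_panel",
    "save_panel",
    "load_panel",
]

PANEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class VariantInfo:
    """A single variant: identifier, position and allele coding.

    ``a1`` is the counted (effect) allele, ``a2`` the other allele.  Positions
    are 1-based base pairs.  ``maf`` is the minor allele frequency in [0, 0.5].
    """

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"variant {self.id}: pos must be positive, got {self.pos}")
        if self.a1 == self.a2:
            raise ValueError(f"variant {self.id}: identical alleles {self.a1!r}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class LDBlock:
    """One genomic block: its variants, correlation matrix R and LD scores.

    The LD score of variant j is the row sum of squared correlations,
    (R^T R)_jj, i.e. the diagonal of the squared LD matrix.
    """

    variants: list[VariantInfo]
    R: np.ndarray
    ld_scores: np.ndarray
    n_ref: int

    @property
    def m(self) -> int:
        return self.R.shape[0]


@dataclass
class EigenSystem:
    """Retained eigen-pairs of one block's LD matrix, eigenvalues descending.

    Components with eigenvalues at or below the floor used at construction are
    dropped; ``n_retained`` is the number kept.  ``U`` has orthonormal columns.
    """

    U: np.ndarray
    D: np.ndarray
    n_retained: int
    block_id: int
    variants: list[VariantInfo] = field(default_factory=list)
    ld_scores: np.ndarray | None = None

    @property
    def m(self) -> int:
        """Number of variants in the block (rows of U)."""
        return self.U.shape[0]


def compute_ld_matrix(
    standardized_genotypes: np.ndarray,
    variants: Sequence[VariantInfo] | None = None,
    n_ref: int | None = None,
) -> LDBlock:
    """Sample correlation matrix R = G'G / n_ref from standardized genotypes.

    Each column must already have mean 0 and variance 1 (computed with
    denominator n).  The diagonal is forced to exactly 1 and LD scores are the
    row sums of R squared entrywise.

    Raises
    ------
    ValueError
        if the matrix is empty or a column has (near) zero variance; the
        message names the offending variant index.
    """
    G = np.asarray(standardized_genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one variant")
    n, m = G.shape
    if n < 2:
        raise ValueError("need at least 2 reference samples")
    col_var = G.var(axis=0)
    bad = np.flatnonzero(np.abs(col_var - 1.0) > 1e-4)
    if bad.size:
        zero = np.flatnonzero(col_var < 1e-12)
        if zero.size:
            raise ValueError(f"zero-variance genotype column(s) at index {zero.tolist()}")
        raise ValueError(f"column(s) {bad.tolist()} not standardized (variance != 1)")
    R = (G.T @ G) / n
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    ld_scores = np.sum(R * R, axis=1)
    if variants is None:
        variants = _placeholder_variants(m)
    return LDBlock(variants=list(variants), R=R, ld_scores=ld_scores, n_ref=n_ref or n)


def _placeholder_variants(m: int, chrom: str = "1", start_pos: int = 1) -> list[VariantInfo]:
    return [
        VariantInfo(id=f"snp{i}", chrom=chrom, pos=start_pos + i, a1="A", a2="G", maf=0.25)
        for i in range(m)
    ]


def ledoit_wolf_intensity(standardized_genotypes: np.ndarray) -> float:
    """Optimal linear-shrinkage intensity toward the identity for a correlation matrix.

    For standardized data X (columns mean 0, variance 1, denominator n) and
    sample correlation S = X'X/n, the Ledoit-Wolf intensity is

        alpha = min(1, b^2 / d^2),
        d^2 = ||S - I||_F^2,
        b^2 = min(d^2, (1/n^2) * sum_i ||x_i x_i' - S||_F^2),

    where x_i are the sample rows.  alpha = 0 when S is already the identity.
    """
    X = np.asarray(standardized_genotypes, dtype=float)
    n, m = X.shape
    S = (X.T @ X) / n
    S = (S + S.T) / 2.0
    d2 = float(np.sum((S - np.eye(m)) ** 2))
    if d2 <= 0.0:
        return 0.0
    # sum_i ||x_i x_i' - S||^2 = sum_i ||x_i||^4 - 2 tr(S X'X) + n ||S||^2
    #                          = sum_i ||x_i||^4 - n ||S||^2
    row_norm4 = float(np.sum(np.sum(X * X, axis=1) ** 2))
    b2 = (row_norm4 / n - float(np.sum(S * S))) / n
    b2 = min(max(b2, 0.0), d2)
    return min(1.0, b2 / d2)


def shrink_ld(
    block: LDBlock,
    intensity: float | str = "auto",
    standardized_genotypes: np.ndarray | None = None,
) -> LDBlock:
    """Linear shrinkage of R toward the identity: R* = (1 - a) R + a I.

    ``intensity="auto"`` estimates the Ledoit-Wolf optimal intensity, which
    requires the reference genotypes the block was built from.  LD scores are
    recomputed from the shrunk matrix.
    """
    if intensity == "auto":
        if standardized_genotypes is None:
            raise ValueError("auto shrinkage requires the reference genotype matrix")
        alpha = ledoit_wolf_intensity(standardized_genotypes)
    else:
        alpha = float(intensity)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"shrinkage intensity {alpha} outside [0, 1]")
    R = (1.0 - alpha) * block.R + alpha * np.eye(block.m)
    np.fill_diagonal(R, 1.0)
    return LDBlock(
        variants=block.variants,
        R=R,
        ld_scores=np.sum(R * R, axis=1),
        n_ref=block.n_ref,
    )


def partition_blocks(
    variants: Sequence[VariantInfo],
    R_band,
    r_threshold: float,
    window_bp: int,
) -> list[tuple[int, int]]:
    """Partition position-sorted variants into contiguous quasi-independent blocks.

    A pair (i, j) is *linked* when |r_ij| > r_threshold and the variants are on
    the same chromosome within ``window_bp`` base pairs.  Single-linkage merging
    of linked pairs yields the minimal set of contiguous, non-overlapping index
    ranges [start, stop) such that no linked pair crosses a boundary.
    Chromosome changes always break blocks.

    ``R_band`` supplies pairwise |r| values as either a dict {(i, j): r}, a
    dense matrix, or a scipy sparse matrix; entries not present are treated as
    unlinked.
    """
    if r_threshold <= 0:
        raise ValueError("r_threshold must be positive")
    variants = list(variants)
    m = len(variants)
    if m == 0:
        return []
    for k in range(1, m):
        if variants[k].chrom == variants[k - 1].chrom and variants[k].pos < variants[k - 1].pos:
            raise ValueError(f"variants not position-sorted at index {k}")

    pairs = _iter_r_pairs(R_band, m)
    # reach[i]: furthest index that must share a block with i
    reach = np.arange(m)
    for i, j, r in pairs:
        if i == j:
            continue
        lo, hi = (i, j) if i < j else (j, i)
        vi, vj = variants[lo], variants[hi]
        if vi.chrom != vj.chrom:
            continue
        if abs(vj.pos - vi.pos) > window_bp:
            continue
        if abs(r) > r_threshold:
            reach[lo] = max(reach[lo], hi)

    # Sweep: a block closes at k when no link started at or before k reaches
    # past k.  Links never span chromosomes, so chromosome ends close blocks.
    ranges: list[tuple[int, int]] = []
    start = 0
    frontier = 0
    for k in range(m):
        frontier = max(frontier, k, int(reach[k]))
        if k == frontier:
            ranges.append((start, k + 1))
            start = k + 1
    return ranges


def _iter_r_pairs(R_band, m: int):
    """Yield (i, j, r) triples from a dict, dense array, or scipy sparse matrix."""
    if isinstance(R_band, dict):
        for (i, j), r in R_band.items():
            yield int(i), int(j), float(r)
        return
    try:
        from scipy import sparse

        if sparse.issparse(R_band):
            coo = R_band.tocoo()
            for i, j, r in zip(coo.row, coo.col, coo.data):
                yield int(i), int(j), float(r)
            return
    except ImportError:  # pragma: no cover
        pass
    A = np.asarray(R_band, dtype=float)
    ii, jj = np.nonzero(A)
    for i, j in zip(ii, jj):
        if i < j:
            yield int(i), int(j), float(A[i, j])


def eigendecompose_block(
    block: LDBlock,
    eigenvalue_floor: float = 1e-6,
    block_id: int = 0,
) -> EigenSystem:
    """Eigen-decompose R = U D U' and drop trivial components (d <= floor).

    Eigenvalues are returned in descending order.  The sum of the *pre-filter*
    eigenvalues equals the block dimension (trace of a correlation matrix); the
    floor removes numerically null principal components only.
    """
    R = block.R
    if not np.all(np.isfinite(R)):
        raise ValueError("LD matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals[0] < -1e-8:
        raise ValueError(f"LD matrix not PSD: smallest eigenvalue {vals[0]:.3e}")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eigenvalue_floor
    return EigenSystem(
        U=np.ascontiguousarray(vecs[:, keep]),
        D=vals[keep].copy(),
        n_retained=int(keep.sum()),
        block_id=block_id,
        variants=block.variants,
        ld_scores=block.ld_scores.copy(),
    )


def build_panel(
    standardized_genotypes: np.ndarray,
    block_ranges: Sequence[tuple[int, int]],
    variants: Sequence[VariantInfo] | None = None,
    shrink: float | str | None = None,
    eigenvalue_floor: float = 1e-6,
) -> list[EigenSystem]:
    """Build a block eigen-system panel from a standardized genotype matrix.

    Each ``(start, stop)`` range becomes one block: sample LD, optional linear
    shrinkage, then eigen-decomposition with the trivial-component floor.
    """
    G = np.asarray(standardized_genotypes, dtype=float)
    if variants is None:
        variants = _placeholder_variants(G.shape[1])
    panel = []
    for b, (start, stop) in enumerate(block_ranges):
        Gb = G[:, start:stop]
        block = compute_ld_matrix(Gb, variants=variants[start:stop])
        if shrink is not None:
            block = shrink_ld(block, intensity=shrink, standardized_genotypes=Gb)
        panel.append(eigendecompose_block(block, eigenvalue_floor=eigenvalue_floor, block_id=b))
    return panel


def panel_variants(panel: Sequence[EigenSystem]) -> list[VariantInfo]:
    """Concatenated variant metadata in panel (block, within-block) order."""
    out: list[VariantInfo] = []
    for es in panel:
        out.extend(es.variants)
    return out


def panel_ld_scores(panel: Sequence[EigenSystem]) -> np.ndarray:
    """Concatenated per-variant LD scores in panel order."""
    parts = []
    for es in panel:
        if es.ld_scores is None:
            raise ValueError(f"block {es.block_id} carries no LD scores")
        parts.append(es.ld_scores)
    return np.concatenate(parts)


def save_panel(
    panel: Sequence[EigenSystem],
    path: str,
    n_ref: int | None = None,
    eigenvalue_floor: float = 1e-6,
    provenance: str = "",
) -> None:
    """Serialize a panel to a single .npz archive with a JSON metadata record.

    The round trip is bit-exact for eigenvalues, eigenvectors and variant
    metadata.  The archive self-describes the format version, eigenvalue floor,
    reference sample size and free-form provenance.
    """
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "format_version": PANEL_FORMAT_VERSION,
        "n_blocks": len(panel),
        "n_ref": n_ref,
        "eigenvalue_floor": eigenvalue_floor,
        "provenance": provenance,
        "variants": [],
    }
    for k, es in enumerate(panel):
        arrays[f"U{k}"] = es.U
        arrays[f"D{k}"] = es.D
        if es.ld_scores is not None:
            arrays[f"L{k}"] = es.ld_scores
        meta["variants"].append(
            [[v.id, v.chrom, int(v.pos), v.a1, v.a2, float(v.maf)] for v in es.variants]
        )
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_panel(path: str) -> list[EigenSystem]:
    """Load a panel saved by :func:`save_panel`; rejects corrupted archives."""
    with np.load(path, allow_pickle=False) as npz:
        if "__meta__" not in npz:
            raise ValueError(f"{path}: not a panel archive (missing metadata)")
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        if meta.get("format_version") != PANEL_FORMAT_VERSION:
            raise ValueError(
                f"{path}: panel format version {meta.get('format_version')} "
                f"!= supported {PANEL_FORMAT_VERSION}"
            )
        n_blocks = meta["n_blocks"]
        panel = []
        for k in range(n_blocks):
            if f"U{k}" not in npz or f"D{k}" not in npz:
                raise ValueError(f"{path}: truncated archive, block {k} missing")
            U = npz[f"U{k}"]
            D = npz[f"D{k}"]
            ld = npz[f"L{k}"] if f"L{k}" in npz else None
            variants = [
                VariantInfo(id=v[0], chrom=v[1], pos=int(v[2]), a1=v[3], a2=v[4], maf=float(v[5]))
                for v in meta["variants"][k]
            ]
            panel.append(
                EigenSystem(
                    U=U, D=D, n_retained=len(D), block_id=k, variants=variants, ld_scores=ld
                )
            )
    return panel
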