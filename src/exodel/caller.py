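"""Read-depth matrices, sample coverage QC and PCA depth normalization.

The normalization follows the XHMM-style scheme: the sample x target depth
matrix is target-mean-centred, the strongest principal components (systematic
capture/batch structure) are projected out, and each sample's residual row is
scaled to unit standard deviation, yielding per-sample per-target z-scores
that a 3-state HMM segments downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DepthMatrix",
    "NormalizedMatrix",
    "sample_coverage_qc",
    "pca_normalize",
]


def _validate_targets(targets: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    if not required.issubset(targets.columns):
        raise ValueError(f"targets need columns {sorted(required)}")
    if (targets["start"] >= targets["end"]).any():
        raise ValueError("every target needs start < end")
    for _, grp in targets.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not (np.diff(starts) > 0).all():
            raise ValueError("targets must be sorted by start within chromosome")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("targets must not overlap within chromosome")
    return targets.reset_index(drop=True)


@dataclass
class DepthMatrix:
    """Mean per-target read depth for a cohort (samples x targets)."""

    samples: list[str]
    targets: pd.DataFrame  # columns chrom, start, end; sorted, non-overlapping
    depth: np.ndarray  # shape (n_samples, n_targets), reads >= 0

    def __post_init__(self) -> None:
        self.targets = _validate_targets(self.targets)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.samples), len(self.targets)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.samples)} samples x {len(self.targets)} targets"
            )
        if (self.depth < 0).any():
            raise ValueError("read depth must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def subset_samples(self, keep: list[str]) -> "DepthMatrix":
        idx = [self.samples.index(s) for s in keep]
        return DepthMatrix(list(keep), self.targets.copy(), self.depth[idx])


@dataclass
class NormalizedMatrix:
    """Per-sample, per-target normalized depth z-scores (same axes as input)."""

    samples: list[str]
    targets: pd.DataFrame
    z: np.ndarray
    n_components_removed: int = 0
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.z).all():
            raise ValueError("normalized matrix must be finite")


def sample_coverage_qc(
    matrix: DepthMatrix,
    min_mean_depth: float = 30.0,
    min_frac_covered: float = 0.70,
    cover_threshold: float = 20.0,
) -> tuple[DepthMatrix, list[str]]:
    """Drop samples with inadequate exome coverage.

    A sample is excluded iff its mean depth is < ``min_mean_depth`` or the
    fraction of targets with depth >= ``cover_threshold`` is below
    ``min_frac_covered``. Survivors are returned unchanged.
    """
    if matrix.n_samples == 0 or matrix.n_targets == 0:
        raise ValueError("empty depth matrix")
    mean_depth = matrix.depth.mean(axis=1)
    frac_covered = (matrix.depth >= cover_threshold).mean(axis=1)
    ok = (mean_depth >= min_mean_depth) & (frac_covered >= min_frac_covered)
    excluded = [s for s, keep in zip(matrix.samples, ok) if not keep]
    if not ok.any():
        raise ValueError("all samples failed coverage QC")
    kept = [s for s, keep in zip(matrix.samples, ok) if keep]
    return matrix.subset_samples(kept), excluded


def pca_normalize(matrix: DepthMatrix, rel_var_threshold: float = 0.7) -> NormalizedMatrix:
    """Remove dominant principal components from centred depth, z-score rows.

    Components whose variance exceeds ``rel_var_threshold`` times the mean
    component variance are treated as systematic (capture batch, overall
    coverage) and subtracted. Samples whose residual row has zero variance
    carry no usable signal and are dropped with a warning.
    """
    if matrix.n_samples < 2 or matrix.n_targets < 2:
        raise ValueError("PCA normalization needs >= 2 samples and >= 2 targets")
    centred = matrix.depth - matrix.depth.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    comp_var = s**2 / max(matrix.n_samples - 1, 1)
    remove = comp_var > rel_var_threshold * comp_var.mean()
    # guard: systematic structure is a minority of the sample dimensions;
    # never project out more than half of them (components come sorted by
    # variance, so the cap keeps the largest)
    max_removable = matrix.n_samples // 2
    if remove.sum() > max_removable:
        remove = np.zeros_like(remove)
        remove[:max_removable] = True
    k = int(remove.sum())
    if k:
        recon = (u[:, remove] * s[remove]) @ vt[remove]
        residual = centred - recon
    else:
        residual = centred
    row_sd = residual.std(axis=1, ddof=0)
    degenerate = row_sd <= 1e-12
    if degenerate.any():
        dropped = [s_ for s_, bad in zip(matrix.samples, degenerate) if bad]
        warnings.warn(f"dropping {len(dropped)} zero-variance sample(s): {dropped}")
    else:
        dropped = []
    keep = ~degenerate
    z = residual[keep] / row_sd[keep][:, None]
    return NormalizedMatrix(
        samples=[s_ for s_, ok in zip(matrix.samples, keep) if ok],
        targets=matrix.targets.copy(),
        z=z,
        n_components_removed=k,
        dropped_samples=dropped,
    )
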