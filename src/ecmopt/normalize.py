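"""From raw counts to the reference-normalized, condition-averaged matrix.

The processing chain mirrors standard bulk RNA-seq practice: filter weakly
expressed genes, depth-normalize with median-of-ratios size factors and apply
a log2 variance-stabilizing-style transform, divide every gene by the most
stable (lowest-CV) gene within each sample to absorb residual depth effects,
and average technical replicates per experimental condition. Stages are
tagged on the matrix and may only move forward.

The depth transform here is log2(count / size_factor + 1); an externally
produced variance-stabilized matrix can be substituted at the same stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DivisionGuardError,
    GroupingError,
    NoReferenceError,
    SizeFactorError,
    ValidationError,
)

STAGES = ("raw", "depth_transformed", "reference_normalized", "condition_averaged")


@dataclass
class ExpressionMatrix:
    """A genes-by-samples expression grid with a processing-stage tag."""

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage == "raw" and (self.data.to_numpy() < 0).any():
            raise ValidationError("raw counts must be non-negative")

    def require_stage(self, *stages: str):
        if self.stage not in stages:
            raise ValidationError(
                f"expected stage in {stages}, got {self.stage!r}"
            )

    def advance(self, data: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValidationError(
                f"stage may only move forward ({self.stage!r} -> {stage!r})"
            )
        return ExpressionMatrix(data, stage)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.stage)

    @property
    def genes(self):
        return list(self.data.index)

    @property
    def samples(self):
        return list(self.data.columns)


def filter_genes(
    raw: ExpressionMatrix,
    min_count: int = 10,
    min_samples: int = 6,
    mode: str = "per_sample",
) -> list[str]:
    """Genes passing the low-expression filter, input order preserved.

    ``mode='per_sample'`` (default) keeps genes whose raw count strictly
    exceeds ``min_count`` in at least ``min_samples`` samples.
    ``mode='total_sum'`` keeps genes whose summed raw count strictly exceeds
    ``min_count`` — the alternative reading of the same filter sentence.
    """
    raw.require_stage("raw")
    vals = raw.data.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError("raw counts must be integers")
    if mode == "per_sample":
        keep = (raw.data > min_count).sum(axis=1) >= min_samples
    elif mode == "total_sum":
        keep = raw.data.sum(axis=1) > min_count
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")
    return list(raw.data.index[keep])


def size_factors(raw: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over genes (restricted to genes positive in
    every sample) of count / geometric-mean-of-that-gene.
    """
    raw.require_stage("raw")
    counts = raw.data.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise SizeFactorError("no gene is positive in all samples")
    sub = counts[all_positive]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=raw.data.columns, name="size_factor")


def depth_normalize_transform(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize and log2-transform: value = log2(count/size_factor + 1)."""
    sf = size_factors(raw)
    vals = np.log2(raw.data.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    return raw.advance(
        pd.DataFrame(vals, index=raw.data.index, columns=raw.data.columns),
        "depth_transformed",
    )


def select_reference_gene(expr: ExpressionMatrix) -> tuple[str, float]:
    """Most stable gene: minimum coefficient of variation across all samples.

    CV = sample standard deviation (n-1 denominator) / mean, computed on the
    depth-transformed values pooled over all provided samples (all donors).
    Genes with mean <= 0 are excluded; ties break lexicographically.
    """
    expr.require_stage("depth_transformed")
    if expr.data.shape[1] < 2:
        raise NoReferenceError("need >= 2 samples to compute a CV")
    mean = expr.data.mean(axis=1)
    sd = expr.data.std(axis=1, ddof=1)
    cv = (sd / mean)[mean > 0].dropna()
    if cv.empty:
        raise NoReferenceError("all genes excluded (mean <= 0)")
    best = cv.min()
    winners = sorted(cv.index[cv == best])
    return winners[0], float(cv.loc[winners[0]])


def reference_normalize(expr: ExpressionMatrix, ref: str) -> ExpressionMatrix:
    """Divide every gene by the reference gene's value within each sample."""
    expr.require_stage("depth_transformed")
    if ref not in expr.data.index:
        raise NoReferenceError(f"reference gene {ref!r} not in matrix")
    denom = expr.data.loc[ref]
    if (denom <= 0).any():
        raise DivisionGuardError(f"reference {ref!r} non-positive in some sample")
    return expr.advance(expr.data.div(denom, axis=1), "reference_normalized")


def average_replicates(
    expr: ExpressionMatrix, groups: pd.Series | dict
) -> ExpressionMatrix:
    """Average technical replicates: one output column per experimental group.

    ``groups`` maps each sample to its group (run) id. Output columns appear
    in first-occurrence order of the groups; every sample must be mapped and
    every group non-empty.
    """
    expr.require_stage("depth_transformed", "reference_normalized", "condition_averaged")
    groups = pd.Series(groups)
    missing = [s for s in expr.data.columns if s not in groups.index]
    if missing:
        raise GroupingError(f"unmapped samples: {missing[:5]}")
    order = list(dict.fromkeys(groups.loc[expr.data.columns]))
    cols = {}
    for g in order:
        members = [s for s in expr.data.columns if groups.loc[s] == g]
        if not members:
            raise GroupingError(f"empty group {g!r}")
        cols[g] = expr.data[members].mean(axis=1)
    out = pd.DataFrame(cols, index=expr.data.index)
    if expr.stage == "condition_averaged":  # re-grouping an averaged matrix
        return ExpressionMatrix(out, "condition_averaged")
    return expr.advance(out, "condition_averaged")
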