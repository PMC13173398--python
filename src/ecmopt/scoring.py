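"""Summary statistics of organoid state.

* SFI, the spheroid formation index: number of spheroids divided by (median
  spheroid volume x total nuclei). Higher SFI means more numerous and/or
  smaller spheroids per nucleus.
* Vinculin density: total marker signal per spheroid normalized to volume.
* Moffitt subtype score: mean expression of basal-like signature genes minus
  mean expression of classical signature genes, per sample; positive scores
  are called basal-like, non-positive classical. Delta scores subtract each
  donor's baseline (Matrigel) score.
* A permutation test associating genes with principal components, with
  Benjamini-Hochberg control at a lenient 0.25 level.
* The differential-expression filter: |log2 fold change| > 0.58 and BH
  adjusted p < 0.05, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import (
    GeneSetError,
    InsufficientDataError,
    PairingError,
    UndefinedScoreError,
    ValidationError,
)
from .normalize import ExpressionMatrix

REQUIRED_SPHEROID_COLUMNS = ("volume_um3", "nuclei")


def _check_spheroids(table: pd.DataFrame):
    missing = [c for c in REQUIRED_SPHEROID_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"spheroid table missing columns {missing}")
    if len(table) == 0:
        raise UndefinedScoreError("empty spheroid table")
    if (table["volume_um3"] <= 0).any():
        raise ValidationError("volumes must be positive")
    if (table["nuclei"] < 0).any():
        raise ValidationError("nuclei counts must be non-negative")


def sfi(table: pd.DataFrame) -> float:
    """Spheroid formation index: N_spheroids / (median volume x total nuclei)."""
    _check_spheroids(table)
    total_nuclei = float(table["nuclei"].sum())
    if total_nuclei <= 0:
        raise UndefinedScoreError("total nuclei is zero")
    return len(table) / (float(table["volume_um3"].median()) * total_nuclei)


def vinculin_density(signal, volume) -> np.ndarray | float:
    """Marker signal per unit volume, per spheroid."""
    signal = np.asarray(signal, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise UndefinedScoreError("volume must be positive")
    out = signal / volume
    return float(out) if out.ndim == 0 else out


@dataclass
class SubtypeScore:
    sample: str
    score: float
    label: str
    delta_vs_baseline: float | None = None


def moffitt_score(
    expr: ExpressionMatrix,
    basal: set[str] | list[str],
    classical: set[str] | list[str],
    zero_label: str = "classical",
) -> pd.DataFrame:
    """Per-sample subtype score: mean(basal) - mean(classical) on transformed counts.

    Signature genes absent from the matrix are dropped with a warning; an
    entirely absent set raises. Positive scores are labelled basal-like,
    negative classical; an exact zero takes ``zero_label``.
    """
    expr.require_stage("depth_transformed", "reference_normalized", "condition_averaged")
    basal_present = [g for g in basal if g in expr.data.index]
    classical_present = [g for g in classical if g in expr.data.index]
    if not basal_present or not classical_present:
        raise GeneSetError("a signature set is empty or entirely absent")
    if len(basal_present) < len(list(basal)) or len(classical_present) < len(list(classical)):
        import warnings

        warnings.warn("signature genes missing from matrix were dropped", stacklevel=2)
    score = expr.data.loc[basal_present].mean(axis=0) - expr.data.loc[
        classical_present
    ].mean(axis=0)
    label = np.where(score > 0, "basal-like", np.where(score < 0, "classical", zero_label))
    return pd.DataFrame({"score": score, "label": label})


def delta_score(
    scores: pd.DataFrame, donors: pd.Series | dict, baseline: pd.Series | dict
) -> pd.Series:
    """Condition score minus the same donor's baseline (e.g. Matrigel) score."""
    donors = pd.Series(donors)
    baseline = pd.Series(baseline)
    deltas = {}
    for sample, row in scores.iterrows():
        if sample not in donors.index:
            raise PairingError(f"sample {sample!r} has no donor assignment")
        donor = donors.loc[sample]
        if donor not in baseline.index:
            raise PairingError(f"donor {donor!r} has no baseline score")
        deltas[sample] = float(row["score"]) - float(baseline.loc[donor])
    return pd.Series(deltas, name="delta_score")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_filter(stats: pd.DataFrame, lfc_threshold: float = 0.58, alpha: float = 0.05) -> list[str]:
    """Genes with |log2FC| strictly above the threshold and BH-adjusted p < alpha.

    ``stats`` needs columns ``log2fc`` and ``pvalue`` (raw); adjustment is
    applied over all rows before filtering.
    """
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValidationError("thresholds must be positive")
    for col in ("log2fc", "pvalue"):
        if col not in stats.columns:
            raise ValidationError(f"stats table missing column {col!r}")
    padj = bh_adjust(stats["pvalue"].to_numpy())
    keep = (stats["log2fc"].abs() > lfc_threshold) & (padj < alpha)
    return list(stats.index[keep])


def welch_de(
    expr: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Two-group Welch t-test on transformed values, as effect/p input to de_filter.

    A deliberately simple surrogate for count-model differential testing:
    log2fc is the difference of group means on the (already log-scale)
    transformed values.
    """
    from scipy import stats as sps

    expr.require_stage("depth_transformed", "reference_normalized")
    a = expr.data[group_a].to_numpy(dtype=float)
    b = expr.data[group_b].to_numpy(dtype=float)
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    return pd.DataFrame(
        {"log2fc": a.mean(axis=1) - b.mean(axis=1), "stat": t, "pvalue": p},
        index=expr.data.index,
    )


def pc_gene_association(
    expr: ExpressionMatrix,
    n_components: int = 2,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.25,
    scheme: str = "loo",
    stat: str = "pearson",
) -> pd.DataFrame:
    """Permutation test of gene-to-principal-component association.

    PCA is run on the samples (genes as features) after dropping
    zero-variance genes. The statistic is the correlation of a gene's
    expression with a PC's sample scores; the null permutes the gene's
    sample order against fixed scores, and empirical p-values
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1) are BH-adjusted per PC with
    significance at adjusted p < alpha.

    ``scheme`` controls which scores a gene is tested against.

    * ``'loo'`` (default): each gene is correlated with PCs computed with
      that gene left out. Because a gene then never contributes to its own
      reference scores, permuting it is an exact test under exchangeability
      and null p-values are uniform.
    * ``'fixed'``: all genes are tested against the one set of PCs computed
      from the full matrix. This is the cheaper, literal construction, but
      on matrices where the leading PCs are noise-driven it is
      anti-conservative: every gene helps shape the PCs it is tested
      against, inflating the observed correlations relative to the
      permutation null.
    """
    expr.require_stage("depth_transformed", "reference_normalized", "condition_averaged")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if scheme not in ("loo", "fixed"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    X = expr.data
    n_samples = X.shape[1]
    if n_samples < 3:
        raise InsufficientDataError("need at least 3 samples")
    X = X[X.std(axis=1, ddof=1) > 0]
    genes = list(X.index)
    n_genes = len(genes)
    M = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def _standardize_rows(A):
        A = A - A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, ddof=1, keepdims=True)
        return A / sd

    def _scores(mat):
        pca = PCA(n_components=n_components, svd_solver="full")
        return pca.fit_transform(mat.T)  # samples x PCs

    if stat == "spearman":
        M_stat = pd.DataFrame(M).rank(axis=1).to_numpy()
    elif stat == "pearson":
        M_stat = M
    else:
        raise ValidationError(f"unknown statistic {stat!r}")
    Zg = _standardize_rows(M_stat)

    def _z_scores(scores):
        if stat == "spearman":
            scores = pd.DataFrame(scores.T).rank(axis=1).to_numpy().T
        return _standardize_rows(scores.T)  # PCs x samples

    if scheme == "fixed":
        # one shared permutation per round across genes (vectorized)
        perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)])
        Zs = _z_scores(_scores(M))  # PCs x samples
        r_obs = (Zg @ Zs.T) / (n_samples - 1)
        exceed = np.zeros_like(r_obs)
        for perm in perms:
            r_perm = (Zg[:, perm] @ Zs.T) / (n_samples - 1)
            exceed += np.abs(r_perm) >= np.abs(r_obs)
    else:  # leave-one-out reference scores, fresh permutations per gene
        r_obs = np.empty((n_genes, n_components))
        exceed = np.zeros((n_genes, n_components))
        keep = np.ones(n_genes, dtype=bool)
        for i in range(n_genes):
            keep[i] = False
            Zs = _z_scores(_scores(M[keep]))
            keep[i] = True
            zi = Zg[i]
            r_obs[i] = (Zs @ zi) / (n_samples - 1)
            perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)])
            r_null = (Zs @ zi[perms].T).T / (n_samples - 1)  # n_perm x PCs
            exceed[i] = (np.abs(r_null) >= np.abs(r_obs[i])[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    padj = np.column_stack([bh_adjust(pvals[:, j]) for j in range(n_components)])
    records = []
    for i, gene in enumerate(genes):
        for j in range(n_components):
            records.append(
                (gene, f"PC{j+1}", r_obs[i, j], pvals[i, j], padj[i, j], padj[i, j] < alpha)
            )
    return pd.DataFrame(
        records, columns=["gene", "pc", "r", "pvalue", "padj", "significant"]
    )
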