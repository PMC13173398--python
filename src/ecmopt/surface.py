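"""Per-gene weighted quadratic response surfaces over peptide composition.

Each gene's (reference-normalized, condition-averaged) expression is modelled
as a full second-order polynomial in the three peptide molarities — intercept,
linear, pairwise-interaction and pure-quadratic terms — fitted by weighted
least squares with weights inversely proportional to the number of design
runs sharing a composition (so the replicated CCD center contributes once,
not nine times). Terms are then pruned by backward stepwise deletion on AIC,
and adjusted R-squared on the training runs serves as the model's
reliability score downstream.

Factors are coded to [-1, 1] internally for numerical conditioning;
coefficients can be reported in raw molarity units via
:meth:`GeneResponseModel.raw_coefficients`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Composition, DesignMatrix, FactorBounds
from .errors import AlignmentError, SingularFitError, UndefinedFitError

#: Fixed basis order for the 10-term quadratic model in factors (C, F, L).
TERMS = ("1", "C", "F", "L", "C:F", "C:L", "F:L", "C^2", "F^2", "L^2")

_AIC_TIE_TOL = 1e-12


def quadratic_basis(x) -> np.ndarray:
    """Expand compositions into the 10-term quadratic basis.

    ``x`` is a Composition, a length-3 vector (C, F, L) or an (n, 3) array;
    returns a 10-vector or an (n, 10) array in the fixed :data:`TERMS` order
    (1, C, F, L, CF, CL, FL, C^2, F^2, L^2).
    """
    if isinstance(x, Composition):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != 3:
        raise ValueError("expected 3 factors (C, F, L)")
    c, f, l = X[:, 0], X[:, 1], X[:, 2]
    B = np.column_stack(
        [np.ones_like(c), c, f, l, c * f, c * l, f * l, c * c, f * f, l * l]
    )
    return B[0] if single else B


@dataclass
class GeneResponseModel:
    """A fitted (possibly reduced) quadratic model for one gene.

    Coefficients are stored in the unit system the model was fitted in
    (coded by default). ``terms`` indexes into :data:`TERMS`; the intercept
    is always included.
    """

    gene: str
    terms: tuple[str, ...]
    coef: np.ndarray
    adjusted_r2: float
    aic: float
    n_obs: int
    rss_w: float
    status: str = "ok"

    def __post_init__(self):
        if "1" not in self.terms:
            raise ValueError("intercept term required")
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.terms):
            raise ValueError("coef/terms length mismatch")

    @property
    def term_indices(self) -> list[int]:
        return [TERMS.index(t) for t in self.terms]

    def full_coef(self) -> np.ndarray:
        """Coefficients as a dense 10-vector (excluded terms zero)."""
        beta = np.zeros(len(TERMS))
        beta[self.term_indices] = self.coef
        return beta

    def predict_basis(self, B: np.ndarray) -> np.ndarray:
        """Predict from precomputed 10-column basis rows."""
        return np.atleast_2d(B) @ self.full_coef()

    def predict(self, x) -> np.ndarray | float:
        """Predict expression at composition(s) ``x`` (same units as the fit)."""
        B = quadratic_basis(x)
        out = self.predict_basis(B)
        return float(out[0]) if B.ndim == 1 else out

    def raw_coefficients(self, bounds: list[FactorBounds]) -> np.ndarray:
        """Re-express a coded-unit model as a dense 10-vector in raw molarity units.

        The quadratic basis is closed under the affine coding map, so the
        coded polynomial expands exactly into raw monomials (a reduced coded
        model may populate raw terms outside its own term set).
        """
        # beta_coded^T phi(code(x)) == (T^T beta_coded)^T phi(x) with
        # phi(code(x)) = T phi(x); T is found exactly from 10 independent points.
        rng = np.random.default_rng(0)
        P = rng.uniform(-1.0, 2.0, size=(30, 3))
        raw_B = quadratic_basis(P)
        coded = np.column_stack([fb.code(P[:, i]) for i, fb in enumerate(bounds)])
        coded_B = quadratic_basis(coded)
        T, *_ = np.linalg.lstsq(raw_B, coded_B, rcond=None)
        return T @ self.full_coef()


def run_weights(design: DesignMatrix, decimals: int = 10) -> pd.Series:
    """Per-run fitting weights: 1 / (number of runs sharing the composition).

    In the 9-center CCD every center run gets weight 1/9 and every other run
    weight 1, which makes the replicated center contribute to the normal
    equations exactly as a single averaged observation would.
    """
    vals = np.round(design.factor_values(), decimals)
    keys = [tuple(row) for row in vals]
    counts: dict[tuple, int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    w = np.array([1.0 / counts[key] for key in keys])
    return pd.Series(w, index=design.runs["run_id"].to_numpy(), name="weight")


def _wls(y, B, w, term_idx):
    """Weighted least squares on selected basis columns; returns (coef, rss_w, rank)."""
    Bsub = B[:, term_idx]
    sw = np.sqrt(w)
    A = Bsub * sw[:, None]
    b = y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ coef
    return coef, float(resid @ resid), rank


def _collinear_terms(B, w, term_idx):
    """Identify basis columns that add no rank, by greedy incremental rank."""
    sw = np.sqrt(w)[:, None]
    kept: list[int] = []
    bad: list[str] = []
    for j in term_idx:
        trial = (B[:, kept + [j]] * sw) if kept else B[:, [j]] * sw
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            bad.append(TERMS[j])
    return bad


def aic_weighted(rss_w: float, n: int, p: int, w) -> float:
    """AIC of a weighted Gaussian linear model with p coefficients.

    AIC = n ln(2 pi RSS_w / n) + n - sum(ln w_i) + 2 (p + 1), the convention
    of R's ``AIC`` on a weighted ``lm`` fit (the residual variance counts as
    an extra estimated parameter). Additive constants are irrelevant to
    deletion ordering but kept for reproducibility.
    """
    w = np.asarray(w, dtype=float)
    rss_w = max(rss_w, 1e-300)  # guard exact interpolation
    return n * math.log(2 * math.pi * rss_w / n) + n - float(np.sum(np.log(w))) + 2 * (p + 1)


def _weighted_tss(y, w):
    ybar = np.average(y, weights=w)
    return float(np.sum(w * (y - ybar) ** 2))


def adjusted_r2(rss_w: float, tss_w: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p), weighted sums of squares.

    ``p`` counts all coefficients including the intercept. A response with
    zero weighted variance yields 1.0 when fitted exactly, else 0.0.
    """
    if n <= p:
        raise UndefinedFitError(f"n={n} <= p={p}")
    if tss_w <= 1e-300:
        return 1.0 if rss_w <= 1e-12 else 0.0
    r2 = 1.0 - rss_w / tss_w
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def fit_weighted(
    y, B, w, gene: str = "", terms: tuple[str, ...] = TERMS
) -> GeneResponseModel:
    """Fit the weighted quadratic model with the given terms.

    ``B`` is the full 10-column basis (rows = runs); ``w`` positive weights.
    Coefficients minimize sum_i w_i (y_i - x_i' beta)^2. Raises
    :class:`SingularFitError` naming the collinear terms if the selected
    columns are rank deficient.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    idx = [TERMS.index(t) for t in terms]
    coef, rss_w, rank = _wls(y, B, w, idx)
    if rank < len(idx):
        raise SingularFitError(_collinear_terms(B, w, idx))
    n, p = len(y), len(idx)
    tss = _weighted_tss(y, w)
    return GeneResponseModel(
        gene=gene,
        terms=tuple(terms),
        coef=coef,
        adjusted_r2=adjusted_r2(rss_w, tss, n, p),
        aic=aic_weighted(rss_w, n, p, w),
        n_obs=n,
        rss_w=rss_w,
    )


# terms whose presence protects a term from deletion, per hierarchy mode
_MARGINALITY_PARENTS = {
    "C": ("C:F", "C:L"),
    "F": ("C:F", "F:L"),
    "L": ("C:L", "F:L"),
}
_STRONG_PARENTS = {
    "C": ("C:F", "C:L", "C^2"),
    "F": ("C:F", "F:L", "F^2"),
    "L": ("C:L", "F:L", "L^2"),
}


def _deletable(terms, hierarchy):
    cands = [t for t in terms if t != "1"]
    if hierarchy == "none":
        return cands
    parents = _MARGINALITY_PARENTS if hierarchy == "marginality" else _STRONG_PARENTS
    return [t for t in cands if not any(h in terms for h in parents.get(t, ()))]


def stepwise_aic(
    y, B, w, full: GeneResponseModel | None = None,
    gene: str = "", hierarchy: str = "marginality",
) -> GeneResponseModel:
    """Backward stepwise deletion on AIC, starting from the full quadratic model.

    At each step the single non-intercept term whose removal most decreases
    AIC is deleted; the path stops when no deletion decreases AIC. Ties
    (within 1e-12) delete the term latest in the fixed basis order. AIC never
    increases along the path, so the returned AIC <= the full-model AIC.

    ``hierarchy`` controls which terms are deletable: ``'marginality'``
    (default) keeps a main effect while any interaction containing it
    remains, the convention of R's backward ``stepAIC`` on a formula model;
    ``'none'`` allows any non-intercept deletion; ``'strong'`` additionally
    lets a pure quadratic protect its main effect.
    """
    if hierarchy not in ("none", "marginality", "strong"):
        raise ValueError(f"unknown hierarchy mode {hierarchy!r}")
    current = full if full is not None else fit_weighted(y, B, w, gene=gene)
    while True:
        best = None
        for t in _deletable(current.terms, hierarchy):
            reduced_terms = tuple(x for x in current.terms if x != t)
            cand = fit_weighted(y, B, w, gene=gene, terms=reduced_terms)
            if best is None or cand.aic < best.aic - _AIC_TIE_TOL or (
                abs(cand.aic - best.aic) <= _AIC_TIE_TOL
                and TERMS.index(t) > TERMS.index(best_removed)
            ):
                best, best_removed = cand, t
        if best is None or best.aic >= current.aic - _AIC_TIE_TOL:
            return current
        current = best


def fit_all_genes(
    expr,
    design: DesignMatrix,
    weights: pd.Series | None = None,
    coded: bool = True,
    stepwise: bool = True,
    hierarchy: str = "marginality",
) -> dict[str, GeneResponseModel]:
    """Fit one response-surface model per gene of a condition-averaged matrix.

    ``expr`` is an :class:`~ecmopt.normalize.ExpressionMatrix` at stage
    ``condition_averaged`` (or a bare genes-by-runs DataFrame) whose columns
    are design run ids. Genes whose fit fails are recorded with
    ``status='failed'`` rather than dropped.
    """
    from .normalize import ExpressionMatrix  # local import to avoid cycle

    if isinstance(expr, ExpressionMatrix):
        expr.require_stage("condition_averaged")
        data = expr.data
    else:
        data = expr
    run_ids = list(design.runs["run_id"])
    if set(data.columns) != set(run_ids):
        raise AlignmentError("expression columns do not match design run ids")
    data = data[run_ids]
    if weights is None:
        weights = run_weights(design)
    w = weights.loc[run_ids].to_numpy(dtype=float)
    X = design.coded_values() if coded else design.factor_values()
    B = quadratic_basis(X)

    models: dict[str, GeneResponseModel] = {}
    for gene, row in data.iterrows():
        y = row.to_numpy(dtype=float)
        try:
            full = fit_weighted(y, B, w, gene=gene)
            models[gene] = (
                stepwise_aic(y, B, w, full=full, gene=gene, hierarchy=hierarchy)
                if stepwise else full
            )
        except (SingularFitError, UndefinedFitError) as exc:
            models[gene] = GeneResponseModel(
                gene=gene, terms=("1",), coef=np.array([np.nan]),
                adjusted_r2=np.nan, aic=np.nan, n_obs=len(y), rss_w=np.nan,
                status=f"failed: {exc}",
            )
    return models


def validate_confirmation(
    models: dict[str, GeneResponseModel],
    observed,
    design: DesignMatrix,
    coded: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Compare model predictions with held-out confirmation observations.

    ``observed`` is a genes-by-runs frame over the confirmation design. No
    refitting occurs. Returns the long predicted/observed table and a pooled
    summary with R^2 (1 - SS_res/SS_tot about the observed mean) and RMSE.
    Compositions outside the design box only trigger a warning upstream;
    prediction is a polynomial and evaluates anywhere.
    """
    from .normalize import ExpressionMatrix

    if isinstance(observed, ExpressionMatrix):
        observed = observed.data
    run_ids = list(design.runs["run_id"])
    if set(observed.columns) != set(run_ids):
        raise AlignmentError("confirmation columns do not match design run ids")
    observed = observed[run_ids]
    X = design.coded_values() if coded else design.factor_values()
    B = quadratic_basis(X)

    records = []
    for gene, row in observed.iterrows():
        model = models.get(gene)
        if model is None or model.status != "ok":
            continue
        pred = model.predict_basis(B)
        for rid, p, o in zip(run_ids, pred, row.to_numpy(dtype=float)):
            records.append((gene, rid, p, o))
    table = pd.DataFrame(records, columns=["gene", "run_id", "predicted", "observed"])
    resid = table["observed"] - table["predicted"]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((table["observed"] - table["observed"].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12 else 0.0)
    rmse = float(np.sqrt(ss_res / len(table))) if len(table) else float("nan")
    return table, {"r2": r2, "rmse": rmse, "n_pairs": len(table)}
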