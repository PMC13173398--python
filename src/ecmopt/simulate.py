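"""Synthetic organoid RNA-seq experiments with known composition-response surfaces.

The generator emulates the structure the downstream pipeline assumes: each
gene's log2 expected expression is an exact quadratic polynomial in the coded
peptide factors (C, F, L), counts are drawn negative-binomially with
gene-wise dispersion (variance = mu + alpha mu^2, the gamma-Poisson
parameterization), samples carry multiplicative sequencing-depth factors,
and gene programs are planted: coordinated EMT-up and EMT-down sets sharing
a common response surface (so the program has a well-defined optimal
composition), basal/classical subtype marker sets, near-noiseless
housekeeping genes, and unresponsive null genes.

The planted optimum — the composition maximizing the mean EMT-up surface
minus the mean EMT-down surface on a dense grid — is recorded in the ground
truth so that end-to-end optimization runs can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Composition, DesignMatrix, FactorBounds
from .errors import ConfigError
from .surface import TERMS, quadratic_basis

PROGRAMS = ("emt_up", "emt_down", "basal", "classical", "housekeeping", "null")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Program sizes and noise levels describe a desk-scale bulk RNA-seq study:
    a few hundred to a couple thousand genes, NB dispersions in the range
    typical of bulk data (0.02-0.1), EMT program amplitudes around one
    twofold change across the design box, and mild (+-40%) library-depth
    variation.
    """

    n_emt_up: int = 20
    n_emt_down: int = 20
    n_basal: int = 25
    n_classical: int = 25
    n_housekeeping: int = 5
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    program_baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    dispersion_range: tuple[float, float] = (0.02, 0.1)
    housekeeping_dispersion: float = 0.002
    #: per-gene scaling of the shared EMT program surface
    program_amplitude_range: tuple[float, float] = (0.6, 1.4)
    #: sd of gene-specific idiosyncratic coefficients on top of the program
    idiosyncratic_sd: float = 0.05
    #: coefficient scale of independently responsive subtype-marker genes
    marker_effect_sd: float = 0.25
    #: curvature / interaction scales of the shared program surface
    program_curvature_range: tuple[float, float] = (0.5, 1.5)
    program_interaction_sd: float = 0.15
    #: planted program optimum is drawn inside this coded sub-box
    optimum_coded_range: tuple[float, float] = (-0.6, 0.6)
    donor_intercept_sd: float = 0.2
    grid_resolution: int = 51

    def program_sizes(self) -> dict[str, int]:
        return {
            "emt_up": self.n_emt_up,
            "emt_down": self.n_emt_down,
            "basal": self.n_basal,
            "classical": self.n_classical,
            "housekeeping": self.n_housekeeping,
        }


@dataclass
class GroundTruthModel:
    """Known per-gene quadratic surfaces and program labels.

    ``beta`` is genes x 10 on the coded [-1, 1] factor scale and log2
    expression scale; ``labels`` maps each gene to its program.
    """

    genes: list[str]
    beta: np.ndarray
    dispersion: np.ndarray
    labels: pd.Series
    bounds: list[FactorBounds]
    planted_optimum: Composition
    config: SimulationConfig
    seed: int

    def program_genes(self, program: str) -> list[str]:
        return list(self.labels.index[self.labels == program])

    def expected_log2_expression(self, design: DesignMatrix) -> pd.DataFrame:
        """Exact noiseless log2 expression surface evaluated at design runs."""
        B = quadratic_basis(design.coded_values())
        vals = self.beta @ B.T
        return pd.DataFrame(vals, index=self.genes, columns=design.runs["run_id"])

    def program_score_surface(self, coded_points: np.ndarray) -> np.ndarray:
        """Mean EMT-up surface minus mean EMT-down surface at coded points."""
        B = quadratic_basis(coded_points)
        up = np.isin(self.genes, self.program_genes("emt_up"))
        down = np.isin(self.genes, self.program_genes("emt_down"))
        centered = self.beta.copy()
        centered[:, 0] = 0.0  # intercepts shift, never shape, the program score
        return (centered[up] @ B.T).mean(axis=0) - (centered[down] @ B.T).mean(axis=0)


@dataclass
class SimulatedExperiment:
    """Raw counts plus the sample sheet and the truth that generated them."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # sample, run_id, donor, replicate, depth_factor
    truth: GroundTruthModel
    seed: int
    donor_shifts: pd.DataFrame | None = None


def _coded_grid(resolution: int) -> np.ndarray:
    axis = np.linspace(-1.0, 1.0, resolution)
    grid = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.column_stack([g.ravel() for g in grid])


def simulate_ground_truth(
    n_genes: int,
    bounds: list[FactorBounds],
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    """Draw a ground-truth model: coefficients, dispersions, program labels.

    EMT-up genes share a common quadratic program surface (scaled per gene,
    plus small idiosyncratic terms); EMT-down genes get the negated surface,
    emulating a coordinately regulated program. Subtype markers respond
    independently; housekeeping genes are flat and near-noiseless; remaining
    genes are intercept-only nulls. The planted optimum is the argmax of the
    mean up-minus-down surface on a dense coded grid, recorded in raw mM.
    """
    config = config or SimulationConfig()
    sizes = config.program_sizes()
    if n_genes < sum(sizes.values()):
        raise ConfigError("n_genes smaller than the sum of program sizes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]

    labels = np.array(["null"] * n_genes, dtype=object)
    start = 0
    for program, size in sizes.items():
        labels[start : start + size] = program
        start += size
    labels = pd.Series(labels, index=genes, name="program")

    beta = np.zeros((n_genes, len(TERMS)))
    lo, hi = config.baseline_log2_range
    beta[:, 0] = rng.uniform(lo, hi, size=n_genes)
    plo, phi = config.program_baseline_log2_range
    programmed = labels.isin(["emt_up", "emt_down", "basal", "classical"]).to_numpy()
    beta[programmed, 0] = rng.uniform(plo, phi, size=programmed.sum())
    beta[(labels == "housekeeping").to_numpy(), 0] = rng.uniform(8.0, 11.0, size=sizes["housekeeping"])

    # Shared EMT program surface: concave quadratic with interior optimum.
    opt = rng.uniform(*config.optimum_coded_range, size=3)
    curv = rng.uniform(*config.program_curvature_range, size=3)
    inter = rng.normal(0.0, config.program_interaction_sd, size=3)
    program_coef = np.zeros(len(TERMS))
    program_coef[1:4] = 2.0 * curv * opt  # linear terms of -(x-opt)' diag(curv) (x-opt)
    program_coef[4:7] = inter
    program_coef[7:10] = -curv

    amp_lo, amp_hi = config.program_amplitude_range
    for gene_idx, gene in enumerate(genes):
        label = labels.iloc[gene_idx]
        if label in ("emt_up", "emt_down"):
            sign = 1.0 if label == "emt_up" else -1.0
            amp = rng.uniform(amp_lo, amp_hi)
            idio = rng.normal(0.0, config.idiosyncratic_sd, size=len(TERMS) - 1)
            beta[gene_idx, 1:] = sign * amp * program_coef[1:] + idio
        elif label in ("basal", "classical"):
            beta[gene_idx, 1:] = rng.normal(0.0, config.marker_effect_sd, size=len(TERMS) - 1)
        # housekeeping and null genes keep all non-intercept terms at zero

    dispersion = rng.uniform(*config.dispersion_range, size=n_genes)
    dispersion[(labels == "housekeeping").to_numpy()] = config.housekeeping_dispersion

    truth = GroundTruthModel(
        genes=genes, beta=beta, dispersion=dispersion, labels=labels,
        bounds=list(bounds), planted_optimum=Composition(1, 1, 1), config=config,
        seed=seed,
    )
    grid = _coded_grid(config.grid_resolution)
    best = grid[int(np.argmax(truth.program_score_surface(grid)))]
    raw = [fb.decode(z) for fb, z in zip(bounds, best)]
    truth.planted_optimum = Composition(*[float(v) for v in raw])
    return truth


def _nb_draw(rng, mu, alpha):
    """Gamma-Poisson draw with variance mu + alpha mu^2 (Poisson when alpha ~ 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_counts(
    truth: GroundTruthModel,
    design: DesignMatrix,
    n_reps: int = 3,
    n_donors: int = 1,
    depth_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
    noise: bool = True,
) -> SimulatedExperiment:
    """Sample a counts matrix over the design runs.

    The expected count of gene g in sample j is
    ``depth_j * 2**(beta_g' phi(x_j) + donor shift)`` with phi the coded
    quadratic basis; counts are NB with the gene's dispersion. Depth factors
    are log-uniform in ``depth_range``. With ``noise=False`` depth factors
    are 1, donor shifts are 0 and counts are the rounded means
    (deterministic).
    """
    if design.n_runs == 0 or n_reps < 1:
        raise ConfigError("design must be non-empty and n_reps >= 1")
    if not (0 < depth_range[0] <= depth_range[1]):
        raise ConfigError("depth_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    eta = truth.expected_log2_expression(design)  # genes x runs
    run_ids = list(design.runs["run_id"])

    donor_shifts = pd.DataFrame(
        rng.normal(0.0, truth.config.donor_intercept_sd, size=(len(truth.genes), n_donors))
        if (noise and n_donors > 1)
        else np.zeros((len(truth.genes), n_donors)),
        index=truth.genes,
        columns=[f"donor{d+1}" for d in range(n_donors)],
    )

    cols, rows = [], []
    counts = np.zeros((len(truth.genes), design.n_runs * n_reps * n_donors), dtype=np.int64)
    j = 0
    log_lo, log_hi = np.log(depth_range[0]), np.log(depth_range[1])
    for d, donor in enumerate(donor_shifts.columns):
        shift = donor_shifts.iloc[:, d].to_numpy()
        for rid in run_ids:
            mu_base = np.power(2.0, eta[rid].to_numpy() + shift)
            for rep in range(1, n_reps + 1):
                depth = float(np.exp(rng.uniform(log_lo, log_hi))) if noise else 1.0
                mu = depth * mu_base
                if noise:
                    col = _nb_vector(rng, mu, truth.dispersion)
                else:
                    col = np.round(mu).astype(np.int64)
                sample = f"{donor}_{rid}_r{rep}"
                counts[:, j] = col
                cols.append(sample)
                rows.append((sample, rid, donor, rep, depth))
                j += 1

    counts_df = pd.DataFrame(counts, index=truth.genes, columns=cols)
    samples = pd.DataFrame(
        rows, columns=["sample", "run_id", "donor", "replicate", "depth_factor"]
    )
    return SimulatedExperiment(
        counts=counts_df, samples=samples, truth=truth, seed=seed,
        donor_shifts=donor_shifts,
    )


def _nb_vector(rng, mu, alpha):
    """Vectorized gamma-Poisson over genes with per-gene dispersion."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty(len(mu), dtype=np.int64)
    poisson_like = alpha < 1e-8
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        lam = rng.gamma(shape=1.0 / alpha[nb], scale=alpha[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_spheroid_table(
    n_spheroids: int,
    volume_law: tuple[float, float] = (10.0, 0.5),
    nuclei_per_volume: float = 2e-3,
    signal_law: tuple[float, float] = (4.0, 0.6),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-spheroid volumes, nuclei counts and marker signal.

    Volumes (um^3) and marker signal are log-normal with the given (log-mean,
    log-sd); nuclei counts are Poisson with rate proportional to volume.
    Returns a table with columns spheroid_id, volume_um3, nuclei, signal.
    """
    if n_spheroids < 1:
        raise ConfigError("n_spheroids must be >= 1")
    if nuclei_per_volume <= 0 or volume_law[1] <= 0 or signal_law[1] <= 0:
        raise ConfigError("rates and spreads must be positive")
    rng = np.random.default_rng(seed)
    volume = rng.lognormal(mean=volume_law[0], sigma=volume_law[1], size=n_spheroids)
    nuclei = rng.poisson(nuclei_per_volume * volume)
    signal = rng.lognormal(mean=signal_law[0], sigma=signal_law[1], size=n_spheroids)
    return pd.DataFrame(
        {
            "spheroid_id": [f"s{i:03d}" for i in range(1, n_spheroids + 1)],
            "volume_um3": volume,
            "nuclei": nuclei,
            "signal": signal,
        }
    )
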