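"""Central composite designs over synthetic-matrix peptide factors.

The experimental system varies three matrix peptides (C, F, L) at three
molarity levels each — low, center (arithmetic midpoint) and high — in a
face-centered central composite design (CCD), while a fourth peptide B is
held at a constant molarity. Confirmation compositions are drawn uniformly
inside the factor box to validate fitted response surfaces out of sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidBoundsError

#: Constant molarity (mM) of peptide B in every composition.
DEFAULT_B_MM = 0.2625

ROLE_FACTORIAL = "factorial"
ROLE_AXIAL = "axial"
ROLE_CENTER = "center"
ROLE_CONFIRMATION = "confirmation"


@dataclass(frozen=True)
class FactorBounds:
    """Molarity range of one peptide factor.

    Parameters
    ----------
    name : factor label, e.g. ``"C"``.
    low, high : molarities in mM; must satisfy ``0 < low < high``.
    """

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (self.low > 0 and self.high > 0):
            raise InvalidBoundsError(f"{self.name}: molarities must be positive")
        if not self.low < self.high:
            raise InvalidBoundsError(f"{self.name}: low must be < high")

    @property
    def mid(self) -> float:
        """Center level: arithmetic midpoint of low and high."""
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, x):
        """Map raw molarity to the coded [-1, 1] scale."""
        return (np.asarray(x, dtype=float) - self.mid) / self.half_range

    def decode(self, z):
        """Map coded [-1, 1] values back to raw molarity."""
        return np.asarray(z, dtype=float) * self.half_range + self.mid

    def contains(self, x) -> bool:
        return bool(self.low <= x <= self.high)


def default_bounds() -> list[FactorBounds]:
    """The study's factor ranges: C in [0.75, 1.5] mM; F and L in [0.15, 0.375] mM."""
    return [
        FactorBounds("C", 0.75, 1.5),
        FactorBounds("F", 0.15, 0.375),
        FactorBounds("L", 0.15, 0.375),
    ]


@dataclass(frozen=True)
class Composition:
    """A synthetic-matrix formulation: molarities (mM) of peptides C, F, L and constant B."""

    c: float
    f: float
    l: float
    b: float = DEFAULT_B_MM

    def as_array(self) -> np.ndarray:
        """Variable factors only, in (C, F, L) order."""
        return np.array([self.c, self.f, self.l], dtype=float)


@dataclass
class DesignMatrix:
    """An ordered table of design runs.

    ``runs`` has columns run_id, role, C_mM, F_mM, L_mM, B_mM; ``factors``
    carries the bounds the design was built from; ``seed`` records the
    randomization seed (None before randomization).
    """

    runs: pd.DataFrame
    factors: list[FactorBounds]
    seed: int | None = None
    b_mm: float = DEFAULT_B_MM
    _factor_cols: list[str] = field(init=False, repr=False)

    def __post_init__(self):
        self._factor_cols = [f"{fb.name}_mM" for fb in self.factors]
        required = {"run_id", "role", *self._factor_cols}
        missing = required - set(self.runs.columns)
        if missing:
            raise ConfigError(f"design table missing columns: {sorted(missing)}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def factor_values(self) -> np.ndarray:
        """Runs x factors array of raw molarities."""
        return self.runs[self._factor_cols].to_numpy(dtype=float)

    def coded_values(self) -> np.ndarray:
        """Runs x factors array on the coded [-1, 1] scale."""
        raw = self.factor_values()
        return np.column_stack(
            [fb.code(raw[:, i]) for i, fb in enumerate(self.factors)]
        )

    def compositions(self) -> list[Composition]:
        vals = self.factor_values()
        return [Composition(*row, b=self.b_mm) for row in vals]

    def subset(self, roles) -> "DesignMatrix":
        keep = self.runs[self.runs["role"].isin(roles)].reset_index(drop=True)
        return DesignMatrix(keep, self.factors, seed=self.seed, b_mm=self.b_mm)


def _runs_frame(rows, factors, b_mm):
    cols = ["run_id", "role"] + [f"{fb.name}_mM" for fb in factors] + ["B_mM"]
    df = pd.DataFrame(rows, columns=cols[:-1])
    df["B_mM"] = b_mm
    return df


def build_ccd(
    bounds: list[FactorBounds], n_center: int, b_mm: float = DEFAULT_B_MM
) -> DesignMatrix:
    """Construct a face-centered central composite design.

    For k factors the design holds 2^k factorial corners, 2k axial points on
    the box faces (axial distance alpha = 1, so every factor takes exactly
    its three levels low/mid/high) and ``n_center`` replicated center points.
    With k=3 and n_center=9 this is the study's 23-run design. Runs are
    returned in canonical (unrandomized) order with run ids assigned before
    any randomization so the original design stays recoverable.
    """
    if len(bounds) < 2:
        raise ConfigError("need at least two factors")
    if n_center < 0:
        raise ConfigError("n_center must be >= 0")
    k = len(bounds)
    rows = []
    idx = 1

    def add(levels, role):
        nonlocal idx
        rows.append((f"run{idx:02d}", role, *levels))
        idx += 1

    for corner in itertools.product(*[(fb.low, fb.high) for fb in bounds]):
        add(corner, ROLE_FACTORIAL)
    for j, fb in enumerate(bounds):
        for level in (fb.low, fb.high):
            point = [b.mid for b in bounds]
            point[j] = level
            add(point, ROLE_AXIAL)
    for _ in range(n_center):
        add([fb.mid for fb in bounds], ROLE_CENTER)

    assert len(rows) == 2**k + 2 * k + n_center
    return DesignMatrix(_runs_frame(rows, bounds, b_mm), list(bounds), b_mm=b_mm)


def randomize_runs(design: DesignMatrix, seed: int) -> DesignMatrix:
    """Return the design with its run order permuted (deterministic per seed)."""
    if design.n_runs == 0:
        raise ConfigError("cannot randomize an empty design")
    rng = np.random.default_rng(seed)
    order = rng.permutation(design.n_runs)
    permuted = design.runs.iloc[order].reset_index(drop=True)
    return DesignMatrix(permuted, design.factors, seed=seed, b_mm=design.b_mm)


def _on_lattice(values, bounds, tol=1e-12) -> bool:
    for x, fb in zip(values, bounds):
        if not any(abs(x - lv) <= tol for lv in (fb.low, fb.mid, fb.high)):
            return False
    return True


def sample_confirmation_runs(
    bounds: list[FactorBounds], k: int, seed: int, b_mm: float = DEFAULT_B_MM
) -> list[Composition]:
    """Draw k out-of-design confirmation compositions.

    Each factor is sampled uniformly within its [low, high] range; any draw
    that lands exactly on a CCD lattice point (all factors at low/mid/high)
    is redrawn, so confirmation compositions never duplicate design runs.
    """
    if k <= 0:
        raise ConfigError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Composition] = []
    while len(out) < k:
        vals = [rng.uniform(fb.low, fb.high) for fb in bounds]
        if _on_lattice(vals, bounds):
            continue
        out.append(Composition(*vals, b=b_mm))
    return out


def confirmation_design(
    bounds: list[FactorBounds],
    k: int,
    seed: int,
    b_mm: float = DEFAULT_B_MM,
    start_index: int = 1,
) -> DesignMatrix:
    """Confirmation compositions packaged as a DesignMatrix (role=confirmation)."""
    comps = sample_confirmation_runs(bounds, k, seed, b_mm=b_mm)
    rows = [
        (f"conf{start_index + i:02d}", ROLE_CONFIRMATION, *comp.as_array())
        for i, comp in enumerate(comps)
    ]
    return DesignMatrix(_runs_frame(rows, bounds, b_mm), list(bounds), seed=seed, b_mm=b_mm)


def concat_designs(a: DesignMatrix, b: DesignMatrix) -> DesignMatrix:
    """Stack two designs over identical factors (e.g. CCD + confirmation runs)."""
    if [fb.name for fb in a.factors] != [fb.name for fb in b.factors]:
        raise ConfigError("factor names differ between designs")
    runs = pd.concat([a.runs, b.runs], ignore_index=True)
    if runs["run_id"].duplicated().any():
        raise ConfigError("duplicate run ids when concatenating designs")
    return DesignMatrix(runs, a.factors, seed=a.seed, b_mm=a.b_mm)
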