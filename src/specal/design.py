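"""Multilevel multifactor calibration designs.

Implements the 25-run five-level design used for multicomponent UV
calibration: every factor column is balanced (each level 5 times) and every
ordered pair of distinct factors enumerates the full 5x5 grid of level
combinations exactly once (mutual orthogonality). Coded levels are mapped
affinely onto per-component concentration ranges, and runs are split into
calibration and validation subsets under a level-coverage constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LEVELS = 5
N_RUNS = N_LEVELS * N_LEVELS
LEVELS = (-2, -1, 0, 1, 2)

#: Component order used throughout: the two actives then the three impurities.
FACTOR_NAMES = ("NZ", "PN", "NZ_impB", "PN_impA", "PN_impB")

#: Calibration concentration ranges (ug/mL) of the eye-drop assay:
#: naphazoline HCl 5-13, pheniramine maleate 10-60, NZ impurity B 1-5,
#: PN impurities A and B 2-14.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "NZ": (5.0, 13.0),
    "PN": (10.0, 60.0),
    "NZ_impB": (1.0, 5.0),
    "PN_impA": (2.0, 14.0),
    "PN_impB": (2.0, 14.0),
}

# Pairwise linearly independent direction vectors over GF(5); columns built
# from distinct directions are mutually orthogonal in the combinatorial sense.
_DIRECTIONS = ((1, 0), (1, 1), (1, 2), (1, 3), (1, 4), (0, 1))
MAX_FACTORS = len(_DIRECTIONS)


@dataclass(frozen=True)
class DesignTable:
    """A 25-run coded design: rows are runs, columns are factors, entries -2..+2."""

    coded_levels: np.ndarray
    factor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        levels = np.asarray(self.coded_levels, dtype=int)
        object.__setattr__(self, "coded_levels", levels)
        if levels.shape != (N_RUNS, len(self.factor_names)):
            raise ValueError(
                f"coded_levels shape {levels.shape} does not match "
                f"({N_RUNS}, {len(self.factor_names)})"
            )

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def validate(self) -> None:
        """Check balance and mutual orthogonality; raise ValueError on failure."""
        lv = self.coded_levels
        for j, name in enumerate(self.factor_names):
            counts = {l: int(np.sum(lv[:, j] == l)) for l in LEVELS}
            if any(c != N_LEVELS for c in counts.values()):
                raise ValueError(f"factor {name!r} is not balanced: {counts}")
        for j in range(self.n_factors):
            for k in range(self.n_factors):
                if j == k:
                    continue
                pairs = {(int(a), int(b)) for a, b in zip(lv[:, j], lv[:, k])}
                if len(pairs) != N_RUNS:
                    raise ValueError(
                        f"factors {self.factor_names[j]!r}/{self.factor_names[k]!r} "
                        f"cover only {len(pairs)}/{N_RUNS} level pairs"
                    )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coded_levels, columns=list(self.factor_names))
        df.insert(0, "run_id", np.arange(1, N_RUNS + 1))
        return df


@dataclass(frozen=True)
class LevelMap:
    """Per-factor concentration ranges; coded level -2 maps to c_min, +2 to c_max."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo <= 0:
                raise ValueError(f"{name}: c_min must be > 0, got {lo}")
            if hi <= lo:
                raise ValueError(f"{name}: c_max must exceed c_min, got ({lo}, {hi})")

    def levels_of(self, factor: str) -> np.ndarray:
        """The five equally spaced concentrations of one factor."""
        lo, hi = self.ranges[factor]
        return lo + (np.array(LEVELS) + 2) * (hi - lo) / 4.0


@dataclass(frozen=True)
class CalibrationSplit:
    calibration_indices: np.ndarray
    validation_indices: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        val = np.asarray(self.validation_indices, dtype=int)
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "validation_indices", val)
        if set(cal) & set(val):
            raise ValueError("calibration and validation sets overlap")
        if sorted(set(cal) | set(val)) != list(range(N_RUNS)):
            raise ValueError("split does not partition the 25 runs")

    def to_frame(self) -> pd.DataFrame:
        role = np.empty(N_RUNS, dtype=object)
        role[self.calibration_indices] = "calibration"
        role[self.validation_indices] = "validation"
        return pd.DataFrame({"run_id": np.arange(1, N_RUNS + 1), "role": role})


def generate_design(
    n_factors: int, factor_names: tuple[str, ...] | None = None
) -> DesignTable:
    """Build the 25-run five-level design for ``n_factors`` factors (2..6).

    Runs are indexed by pairs (a, b) over GF(5); factor j takes level
    (alpha_j*a + beta_j*b) mod 5, recoded to -2..+2, with the direction
    vectors (alpha_j, beta_j) pairwise linearly independent. Any two columns
    therefore enumerate all 25 ordered level pairs exactly once, and the
    construction is fully deterministic.
    """
    if not 2 <= n_factors <= MAX_FACTORS:
        raise ValueError(
            f"n_factors must be in 2..{MAX_FACTORS}, got {n_factors}"
        )
    if factor_names is None:
        factor_names = tuple(
            FACTOR_NAMES[: n_factors]
            if n_factors <= len(FACTOR_NAMES)
            else FACTOR_NAMES + tuple(f"F{j}" for j in range(len(FACTOR_NAMES), n_factors))
        )
    if len(factor_names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    levels = np.empty((N_RUNS, n_factors), dtype=int)
    for i in range(N_RUNS):
        a, b = divmod(i, N_LEVELS)
        for j, (alpha, beta) in enumerate(_DIRECTIONS[:n_factors]):
            levels[i, j] = (alpha * a + beta * b) % N_LEVELS - 2
    table = DesignTable(coded_levels=levels, factor_names=factor_names)
    table.validate()
    return table


def realize_concentrations(design: DesignTable, level_map: LevelMap) -> np.ndarray:
    """Map coded levels to concentrations (ug/mL), runs x factors.

    Entry (i, j) = c_min_j + (level + 2) * (c_max_j - c_min_j) / 4, so the
    realization is affine in the coded level and exact at both endpoints.
    """
    missing = [n for n in design.factor_names if n not in level_map.ranges]
    if missing:
        raise ValueError(f"level map missing factors: {missing}")
    conc = np.empty(design.coded_levels.shape, dtype=float)
    for j, name in enumerate(design.factor_names):
        lo, hi = level_map.ranges[name]
        conc[:, j] = lo + (design.coded_levels[:, j] + 2) * (hi - lo) / 4.0
    if np.any(conc <= 0):
        raise ValueError("realized concentrations must be strictly positive")
    return conc


def _loo_full_rank(cal_levels: np.ndarray) -> bool:
    """True if every leave-one-out subset spans the full affine factor space."""
    n, k = cal_levels.shape
    for i in range(n):
        sub = np.delete(cal_levels, i, axis=0).astype(float)
        centered = sub - sub.mean(axis=0)
        if np.linalg.matrix_rank(centered) < k:
            return False
    return True


def split_runs(
    design: DesignTable,
    n_validation: int = 10,
    seed: int = 0,
    max_draws: int = 1000,
) -> CalibrationSplit:
    """Seeded random calibration/validation split with coverage constraints.

    Redraws until (a) every level of every factor appears at least once among
    the calibration runs, so validation predictions never extrapolate beyond
    the calibrated concentration ranges, and (b) the calibration runs still
    span the full factor space after deleting any single run, so
    leave-one-out cross-validation never turns a fold into an extrapolation.
    """
    if not 0 < n_validation < N_RUNS:
        raise ValueError(f"n_validation must be in 1..{N_RUNS - 1}, got {n_validation}")
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        val = rng.choice(N_RUNS, size=n_validation, replace=False)
        cal = np.setdiff1d(np.arange(N_RUNS), val)
        cal_levels = design.coded_levels[cal]
        if all(
            set(LEVELS) <= set(cal_levels[:, j].tolist())
            for j in range(design.n_factors)
        ) and _loo_full_rank(cal_levels):
            return CalibrationSplit(
                calibration_indices=np.sort(cal), validation_indices=np.sort(val)
            )
    raise RuntimeError(
        f"could not satisfy level coverage within {max_draws} draws "
        f"(n_validation={n_validation} may be too large)"
    )
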