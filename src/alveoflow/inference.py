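"""Structure-from-function inversion of the connectivity regressions.

Given an observed (capillary velocity, pressure drop) pair, the velocity
regression — common to all connectivity model sets — yields an estimate of
the total arteriolar cross-sectional area A.  The pressure-drop regressions
differ between model sets, so each set produces its own area estimate; a
candidate vessel configuration (n vessels of diameter d) is retained only if
the pressure-implied area of its model set agrees with the velocity-implied
area.  The outcome is typically a unique configuration or two alternatives
(number-based vs diameter-based) for the same lumen area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import (InconsistentObservationError, InvalidGeometryError,
                     OutOfRangeError)
from .experiments import RegressionModel

__all__ = [
    "Observation",
    "CandidateConfiguration",
    "InferenceResult",
    "invert_regression",
    "enumerate_candidates",
    "infer",
    "DEFAULT_DIAMETER_GRID",
    "DEFAULT_NUMBER_GRID",
]

DEFAULT_DIAMETER_GRID = (20.0, 30.0, 40.0, 50.0, 60.0)
DEFAULT_NUMBER_GRID = (1, 2, 3, 4, 5)
_BASE_DIAMETER = 20.0   # diameter held fixed in the number-varying sets


@dataclass(frozen=True)
class Observation:
    """Measured capillary velocity (mm/s) and pressure drop (mmHg)."""

    v_obs: float
    dp_obs: float
    v_sd: float | None = None
    dp_sd: float | None = None

    def __post_init__(self):
        if self.v_obs <= 0 or self.dp_obs <= 0:
            raise InvalidGeometryError("observations must be positive")


@dataclass(frozen=True)
class CandidateConfiguration:
    n_art: int
    d_art: float
    n_ven: int
    d_ven: float
    A_art: float
    velocity_ok: bool = True
    pressure_ok: bool = False

    @classmethod
    def symmetric(cls, n: int, d: float, **kw) -> "CandidateConfiguration":
        A = n * math.pi * (0.5 * d) ** 2
        return cls(n_art=n, d_art=d, n_ven=n, d_ven=d, A_art=A, **kw)


@dataclass
class InferenceResult:
    A_from_velocity: float                     # µm²
    A_interval: tuple | None                   # (lo, hi) from residual s.d.
    A_from_pressure: dict                      # model_set -> µm²
    candidates: list                           # all velocity-consistent, with flags
    verdict: str                               # {"unique", "two_alternatives", "none"}

    @property
    def consistent(self) -> list:
        """Candidates whose model set also agrees with the pressure drop."""
        return [c for c in self.candidates if c.pressure_ok]

    @property
    def rejected(self) -> list:
        return [c for c in self.candidates if not c.pressure_ok]


def invert_regression(value: float, regression: RegressionModel):
    """A = (value − intercept)/slope, with a ±1 s.d. interval if available.

    Returns (A, interval); raises if the implied area is not positive.
    """
    if regression.slope <= 0:
        raise InvalidGeometryError("regression slope must be positive to invert")
    A = (value - regression.intercept) / regression.slope
    if A <= 0:
        raise OutOfRangeError(
            f"value {value:g} implies non-positive area {A:g}")
    interval = None
    if regression.residual_sd:
        half = regression.residual_sd / regression.slope
        interval = (A - half, A + half)
    return A, interval


def enumerate_candidates(A_target: float, tol: float = 0.10,
                         d_grid=DEFAULT_DIAMETER_GRID,
                         n_grid=DEFAULT_NUMBER_GRID) -> list:
    """All (n, d) on the swept grid with lumen area within ``tol`` of target."""
    if A_target <= 0:
        raise OutOfRangeError("target area must be positive")
    out = []
    for n in n_grid:
        for d in d_grid:
            A = n * math.pi * (0.5 * d) ** 2
            if abs(A - A_target) / A_target <= tol:
                out.append(CandidateConfiguration.symmetric(int(n), float(d)))
    return out


def _sets_for_candidate(cand: CandidateConfiguration, pressure_sets) -> list:
    """Model sets whose pressure regression applies to this candidate."""
    number_like = [s for s in pressure_sets if s.endswith("number")]
    diameter_like = [s for s in pressure_sets if s.endswith("diameter")]
    sets = []
    if cand.d_art == _BASE_DIAMETER:
        sets += number_like
    if cand.n_art == 1:
        sets += diameter_like
    return sets or list(pressure_sets)


def infer(obs: Observation, regressions: dict, tol: float = 0.10,
          d_grid=DEFAULT_DIAMETER_GRID, n_grid=DEFAULT_NUMBER_GRID) -> InferenceResult:
    """Combine velocity and pressure-drop regressions into candidate configurations.

    ``regressions`` holds the pooled velocity fit under ``"velocity"`` and a
    mapping model_set -> pressure-drop fit under ``"pressure"`` (at least two
    sets).  Every grid configuration whose lumen area matches the
    velocity-implied area enters the candidate list; its ``pressure_ok`` flag
    records whether the pressure regression of its own model set implies an
    area that agrees with the velocity-implied one within ``tol``.  The
    verdict counts only pressure-consistent candidates.
    """
    vel_reg: RegressionModel = regressions["velocity"]
    pressure: dict = regressions["pressure"]
    if len(pressure) < 2:
        raise InvalidGeometryError("need pressure regressions for >= 2 model sets")
    A_v, interval = invert_regression(obs.v_obs, vel_reg)
    A_p: dict = {}
    for ms, reg in pressure.items():
        try:
            A_p[ms], _ = invert_regression(obs.dp_obs, reg)
        except OutOfRangeError:
            A_p[ms] = float("nan")

    candidates = []
    for cand in enumerate_candidates(A_v, tol=tol, d_grid=d_grid, n_grid=n_grid):
        ok = False
        for ms in _sets_for_candidate(cand, A_p.keys()):
            a = A_p[ms]
            if a == a and abs(a - A_v) / A_v <= tol:  # a==a filters NaN
                ok = True
                break
        candidates.append(CandidateConfiguration(
            n_art=cand.n_art, d_art=cand.d_art, n_ven=cand.n_ven,
            d_ven=cand.d_ven, A_art=cand.A_art, velocity_ok=True,
            pressure_ok=ok))

    if not candidates:
        raise InconsistentObservationError(
            "no swept configuration matches the velocity observation")
    n_ok = sum(1 for c in candidates if c.pressure_ok)
    verdict = {1: "unique", 2: "two_alternatives"}.get(n_ok, "none")
    return InferenceResult(A_from_velocity=A_v, A_interval=interval,
                           A_from_pressure=A_p, candidates=candidates,
                           verdict=verdict)
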