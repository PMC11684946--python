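"""Connectivity sweeps, sensitivity analyses and target-vs-area regressions.

The study design: starting from the default configuration (one 20-µm
arteriole opposite one 20-µm venule), either the number of vessels (1–5) or
their diameter (20–60 µm by 10) is varied, symmetrically or for one vessel
type at a time, on four geometry replicates (two fresh pore layouts plus
their mirror images).  Mean capillary speed and arteriole-to-venule pressure
drop are regressed against total arteriolar cross-sectional area
A = n·π(d/2)² by ordinary least squares over the replicate-level rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlveoflowError, InsufficientDataError, InvalidGeometryError
from .geometry import (ConnectivityConfig, MorphoParams, build_pillar_lattice,
                       build_sheet_midsurface, mirror_domain, place_pores,
                       place_ports)
from .sheetflow import (BoundaryConditions, FluidModel, SheetFlowProblem,
                        solve_sheet)

__all__ = [
    "SweepSpec",
    "RegressionModel",
    "MODEL_SETS",
    "SENSITIVITY_GRIDS",
    "build_replicate_domain",
    "run_sweep",
    "run_full_study",
    "run_sensitivity",
    "fit_regression",
    "pooled_velocity_regression",
    "regression_table",
]

MODEL_SETS = ("sym_number", "sym_diameter", "asym_art_number",
              "asym_art_diameter", "asym_ven_number", "asym_ven_diameter")

#: parameter grids of the sensitivity study (SI units)
SENSITIVITY_GRIDS = {
    "inlet_velocity": np.arange(0.5e-3, 3.0e-3 + 1e-9, 0.25e-3),   # m/s
    "outlet_pressure": np.arange(500.0, 1500.0 + 1e-9, 100.0),     # Pa
    "density": np.arange(500.0, 1500.0 + 1e-9, 100.0),             # kg/m³
    "viscosity": np.arange(1.0e-3, 56.0e-3 + 1e-9, 5.5e-3),        # Pa·s
}


@dataclass(frozen=True)
class SweepSpec:
    """One connectivity model set with its grids and replicate scheme."""

    model_set: str = "sym_number"
    numbers: tuple = (1, 2, 3, 4, 5)
    diameters: tuple = (20.0, 30.0, 40.0, 50.0, 60.0)
    replicate_seeds: tuple = (11, 12)
    include_mirrors: bool = True

    def __post_init__(self):
        if self.model_set not in MODEL_SETS:
            raise InvalidGeometryError(f"unknown model set {self.model_set!r}")

    def configs(self) -> list[ConnectivityConfig]:
        ms = self.model_set
        if ms == "sym_number":
            return [ConnectivityConfig(n_arterioles=n, n_venules=n)
                    for n in self.numbers]
        if ms == "sym_diameter":
            return [ConnectivityConfig(d_arteriole=d, d_venule=d)
                    for d in self.diameters]
        if ms == "asym_art_number":
            return [ConnectivityConfig(n_arterioles=n) for n in self.numbers]
        if ms == "asym_art_diameter":
            return [ConnectivityConfig(d_arteriole=d) for d in self.diameters]
        if ms == "asym_ven_number":
            return [ConnectivityConfig(n_venules=n) for n in self.numbers]
        return [ConnectivityConfig(d_venule=d) for d in self.diameters]

    def replicates(self) -> list[tuple[int, bool]]:
        reps = [(s, False) for s in self.replicate_seeds]
        if self.include_mirrors:
            reps += [(s, True) for s in self.replicate_seeds]
        return reps


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of a hemodynamic target against arteriolar area A (µm²)."""

    target: str                # {"velocity", "pressure_drop"}
    model_set: str
    slope: float               # mm/s per µm² or mmHg per µm²
    intercept: float
    residual_sd: float
    n_points: int

    def predict(self, A: float) -> float:
        return self.intercept + self.slope * A


def build_replicate_domain(config: ConnectivityConfig,
                           params: MorphoParams | None = None,
                           seed: int = 11, mirrored: bool = False,
                           target_edge_length: float = 4.0,
                           lattice_type: str = "square"):
    """Geometry pipeline for one replicate of one connectivity configuration."""
    params = params or MorphoParams()
    base = params.solve_base()
    lattice = build_pillar_lattice(params, lattice_type)
    R_mid = base.sphere_radius + 0.5 * params.sheet_height
    ports = place_ports(base, config, mid_surface_radius=R_mid)
    pores = place_pores(base, params.n_pores, params.pore_diameter,
                        seed=seed, exclusions=ports)
    domain = build_sheet_midsurface(base, pores, ports, target_edge_length,
                                    params.sheet_height, lattice=lattice)
    return mirror_domain(domain) if mirrored else domain


def _config_key(c: ConnectivityConfig) -> tuple:
    return (c.n_arterioles, c.d_arteriole, c.n_venules, c.d_venule,
            c.arteriole_azimuths, c.venule_azimuths)


def run_sweep(spec: SweepSpec, params: MorphoParams | None = None,
              fluid: FluidModel | None = None,
              bc: BoundaryConditions | None = None,
              target_edge_length: float = 4.0,
              solver: str = "sheet",
              cache: dict | None = None) -> pd.DataFrame:
    """One solve per configuration per replicate; deterministic given seeds.

    Solver failures are recorded per row (``error`` column) and the sweep
    continues.  A shared ``cache`` deduplicates configurations that appear in
    several model sets (notably the default configuration).
    """
    params = params or MorphoParams()
    fluid = fluid or FluidModel()
    bc = bc or BoundaryConditions()
    cache = cache if cache is not None else {}
    rows = []
    for config in spec.configs():
        for seed, mirrored in spec.replicates():
            key = (_config_key(config), seed, mirrored, solver,
                   fluid.rheology, target_edge_length)
            row = {
                "model_set": spec.model_set,
                "n_art": config.n_arterioles, "d_art": config.d_arteriole,
                "n_ven": config.n_venules, "d_ven": config.d_venule,
                "A_art": config.arteriolar_area,
                "seed": seed, "mirrored": mirrored,
            }
            if key in cache:
                row.update(cache[key])
            else:
                try:
                    result = _solve_one(config, params, fluid, bc,
                                        target_edge_length, seed, mirrored,
                                        solver)
                except AlveoflowError as exc:
                    result = {"mean_capillary_speed_mm_s": np.nan,
                              "pressure_drop_mmhg": np.nan,
                              "error": f"{type(exc).__name__}: {exc}"}
                cache[key] = result
                row.update(result)
            rows.append(row)
    return pd.DataFrame(rows)


def _solve_one(config, params, fluid, bc, target_edge_length, seed, mirrored,
               solver) -> dict:
    if solver == "tube":
        from .tubeflow import build_tube_network, solve_network
        net = build_tube_network(params.solve_base(), params, config, seed=seed)
        sol = solve_network(net, fluid, bc)
        return {"mean_capillary_speed_mm_s": sol.mean_capillary_speed_mm_s,
                "pressure_drop_mmhg": sol.pressure_drop_mmhg,
                "mass_balance_residual": sol.node_balance_residual,
                "error": ""}
    domain = build_replicate_domain(config, params, seed=seed,
                                    mirrored=mirrored,
                                    target_edge_length=target_edge_length)
    problem = SheetFlowProblem(domain=domain, fluid=fluid, bc=bc)
    sol = solve_sheet(problem)
    out = {"mean_capillary_speed_mm_s": sol.mean_capillary_speed_mm_s,
           "pressure_drop_mmhg": sol.pressure_drop_mmhg,
           "mass_balance_residual": sol.mass_balance_residual,
           "error": ""}
    for k, v in sol.position_speeds.items():
        out[f"speed_{k}_mm_s"] = v * 1e3
    return out


def run_full_study(model_sets: tuple = MODEL_SETS,
                   params: MorphoParams | None = None,
                   fluid: FluidModel | None = None,
                   bc: BoundaryConditions | None = None,
                   replicate_seeds: tuple = (11, 12),
                   target_edge_length: float = 4.0) -> pd.DataFrame:
    """All requested model sets with a shared solve cache."""
    cache: dict = {}
    frames = [run_sweep(SweepSpec(model_set=ms, replicate_seeds=replicate_seeds),
                        params=params, fluid=fluid, bc=bc,
                        target_edge_length=target_edge_length, cache=cache)
              for ms in model_sets]
    return pd.concat(frames, ignore_index=True)


def run_sensitivity(parameter: str, grid=None,
                    params: MorphoParams | None = None,
                    target_edge_length: float = 4.0,
                    seed: int = 11) -> pd.DataFrame:
    """Vary one boundary condition / fluid property on the default geometry.

    Grids default to the study's printed ranges: inlet velocity 0.5–3 mm/s by
    0.25; outlet pressure 500–1,500 Pa by 100; density 500–1,500 kg/m³ by
    100; viscosity 1–56 cP by 5.5.
    """
    if parameter not in SENSITIVITY_GRIDS:
        raise InvalidGeometryError(f"unknown sensitivity parameter {parameter!r}")
    values = np.asarray(SENSITIVITY_GRIDS[parameter] if grid is None else grid,
                        dtype=float)
    domain = build_replicate_domain(ConnectivityConfig(), params, seed=seed,
                                    target_edge_length=target_edge_length)
    rows = []
    for val in values:
        fluid = FluidModel()
        bc = BoundaryConditions()
        if parameter == "inlet_velocity":
            bc = BoundaryConditions(inlet_velocity=float(val))
        elif parameter == "outlet_pressure":
            bc = BoundaryConditions(outlet_pressure=float(val))
        elif parameter == "density":
            fluid = FluidModel(density=float(val))
        else:
            fluid = FluidModel(mu=float(val))
        problem = SheetFlowProblem(domain=domain, fluid=fluid, bc=bc)
        sol = solve_sheet(problem)
        rows.append({
            "parameter": parameter, "value": float(val),
            "mean_capillary_speed_mm_s": sol.mean_capillary_speed_mm_s,
            "pressure_drop_mmhg": sol.pressure_drop_mmhg,
            "mass_balance_residual": sol.mass_balance_residual,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = {"velocity": "mean_capillary_speed_mm_s",
                   "pressure_drop": "pressure_drop_mmhg"}


def fit_regression(result: pd.DataFrame, target: str,
                   model_set: str) -> RegressionModel:
    """OLS of a target vs arteriolar area over one model set's replicate rows."""
    col = _TARGET_COLUMNS[target]
    df = result[(result["model_set"] == model_set) & result[col].notna()]
    if df["A_art"].nunique() < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct areas, got {df['A_art'].nunique()}")
    fit = stats.linregress(df["A_art"].to_numpy(), df[col].to_numpy())
    resid = df[col] - (fit.intercept + fit.slope * df["A_art"])
    sd = float(np.sqrt((resid ** 2).sum() / max(1, len(df) - 2)))
    return RegressionModel(target=target, model_set=model_set,
                           slope=float(fit.slope), intercept=float(fit.intercept),
                           residual_sd=sd, n_points=len(df))


def pooled_velocity_regression(result: pd.DataFrame) -> RegressionModel:
    """Velocity fit pooled over the arteriole-varying model sets.

    The per-set velocity regressions overlap to the point of being
    indistinguishable, so the inversion uses a single pooled fit.
    """
    pool_sets = [ms for ms in ("sym_number", "sym_diameter",
                               "asym_art_number", "asym_art_diameter")
                 if (result["model_set"] == ms).any()]
    col = _TARGET_COLUMNS["velocity"]
    df = result[result["model_set"].isin(pool_sets) & result[col].notna()]
    if df["A_art"].nunique() < 3:
        raise InsufficientDataError("need >= 3 distinct areas for pooled fit")
    fit = stats.linregress(df["A_art"].to_numpy(), df[col].to_numpy())
    resid = df[col] - (fit.intercept + fit.slope * df["A_art"])
    sd = float(np.sqrt((resid ** 2).sum() / max(1, len(df) - 2)))
    return RegressionModel(target="velocity", model_set="pooled",
                           slope=float(fit.slope), intercept=float(fit.intercept),
                           residual_sd=sd, n_points=len(df))


def regression_table(result: pd.DataFrame) -> dict:
    """Pooled velocity fit plus per-set pressure-drop fits, for inference."""
    pressure = {}
    for ms in MODEL_SETS:
        if not (result["model_set"] == ms).any():
            continue
        sub = result[result["model_set"] == ms]
        if sub["A_art"].nunique() < 3:
            continue
        pressure[ms] = fit_regression(result, "pressure_drop", ms)
    return {"velocity": pooled_velocity_regression(result),
            "pressure": pressure}
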