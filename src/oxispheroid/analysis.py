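"""Downstream experiments and statistics.

Two headline studies sit on top of the geometry and transport layers:

* a diameter sweep — steady minimum oxygen pressure versus spheroid
  diameter, interpolated with bounded decreasing isotonic regression to
  locate the diameters at which the minimum pressure crosses the hypoxia
  thresholds (100 mmHg: end of the safe range; 50 mmHg: onset of necrosis);

* a surface-noise study — transient simulations over a design of Gardner
  noise parameters (a, q, p), each summarised by the early-time linear
  dynamics P̂(t) = A + B·t of the spatial-minimum pressure, with the
  influence of a, q, p on A and B assessed by OLS with Bonferroni-corrected
  t-tests and by Automatic Relevance Determination (sparse Bayesian linear
  regression).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import ARDRegression

from .geometry import (
    BlendParams,
    FusionSpec,
    GardnerNoiseParams,
    GARDNER_FACTOR_BOUND,
    SpheroidSpec,
    fused_spheroids,
    noisy_spheroid,
    sphere,
)
from .grid import GridSpec
from .solver import (
    SimulationConfig,
    TimeSeries,
    build_domain,
    min_pressure,
    simulate,
    solve_steady,
)

__all__ = [
    "SweepResult",
    "ThresholdReport",
    "LinearFit",
    "OLSReport",
    "ARDFit",
    "IsotonicFit",
    "diameter_sweep",
    "analytic_sweep",
    "crossing_diameter",
    "classify_thresholds",
    "fit_linear_dynamics",
    "factorial_noise_design",
    "random_noise_design",
    "noise_study",
    "ols_test",
    "ard_fit",
    "isotonic_fit",
]

PRESSURE_BOUNDS = (0.0, 160.0)  # mmHg: vacuum floor, sea-level atmosphere ceiling


# ---------------------------------------------------------------------------
# diameter sweep and hypoxia thresholds


@dataclass(frozen=True)
class SweepResult:
    """Minimum steady pressure per spheroid diameter for one geometry kind."""

    kind: str                    # "single" or "fused"
    table: pd.DataFrame          # columns: diameter_um, min_pressure_mmHg

    def __post_init__(self):
        d = self.table["diameter_um"].to_numpy()
        if len(d) and not np.all(np.diff(d) > 0):
            raise ValueError("sweep diameters must be strictly increasing")


@dataclass(frozen=True)
class ThresholdReport:
    """Crossing diameters and the safe / hypoxia-forming / necrotic ranges."""

    kind: str
    thresholds: tuple[float, float]       # (low, high) mmHg, e.g. (50, 100)
    crossing_low_um: float | None         # diameter where fit hits the low threshold
    crossing_high_um: float | None        # diameter where fit hits the high threshold
    safe_max_um: float | None             # largest diameter with fit > high threshold
    forming_range_um: tuple[float, float] | None
    necrotic_min_um: float | None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "thresholds_mmHg": list(self.thresholds),
            "crossing_low_um": self.crossing_low_um,
            "crossing_high_um": self.crossing_high_um,
            "safe_max_um": self.safe_max_um,
            "forming_range_um": list(self.forming_range_um) if self.forming_range_um else None,
            "necrotic_min_um": self.necrotic_min_um,
        }


def _fused_model(diameter: float):
    """Symmetric fusion geometry scaled with diameter: two spheroids of the
    given diameter, centers 1.5·R apart, blend a0 = 0.2·R, a1 = a2 = R."""
    R = diameter / 2.0
    return fused_spheroids(FusionSpec.symmetric(radius=R))


def diameter_sweep(kind: str, diameters, cells_per_radius: int = 20,
                   config: SimulationConfig | None = None) -> SweepResult:
    """Steady-state minimum pressure for each diameter (μm).

    ``kind`` is ``"single"`` (smooth sphere) or ``"fused"`` (two equal
    spheroids at 1.5·R center separation with the default blend, everything
    scaling with diameter).  The geometry is held fixed during each solve.
    """
    config = config or SimulationConfig()
    diameters = np.asarray(sorted(float(d) for d in diameters))
    if len(diameters) < 3:
        raise ValueError("diameter sweep requires at least 3 diameters")
    if kind not in ("single", "fused"):
        raise ValueError("kind must be 'single' or 'fused'")
    rows = []
    for d_um in diameters:
        R = d_um / 2.0
        model = sphere((0, 0, 0), R) if kind == "single" else _fused_model(d_um)
        grid = GridSpec.for_model(model, spacing=R / cells_per_radius, pad_cells=2)
        domain = build_domain(model, grid, boundary_offset=config.boundary_offset)
        field = solve_steady(domain, config)
        rows.append((d_um, min_pressure(field)))
    table = pd.DataFrame(rows, columns=["diameter_um", "min_pressure_mmHg"])
    return SweepResult(kind=kind, table=table)


def analytic_sweep(diameters, config: SimulationConfig | None = None) -> SweepResult:
    """Closed-form single-sphere sweep: center pressure P_b − OCR·R²/(6D),
    clipped at zero.  Used as an oracle and as the CLI's --analytic mode."""
    config = config or SimulationConfig()
    diameters = np.asarray(sorted(float(d) for d in diameters))
    R_m = diameters / 2.0 * 1e-6
    p = config.P_boundary - config.OCR * R_m ** 2 / (6.0 * config.D)
    if config.clamp_nonnegative:
        p = np.maximum(p, 0.0)
    table = pd.DataFrame({"diameter_um": diameters, "min_pressure_mmHg": p})
    return SweepResult(kind="single", table=table)


def crossing_diameter(sweep: SweepResult, threshold: float) -> float:
    """Diameter at which the decreasing isotonic fit of the sweep equals the
    threshold pressure, by linear interpolation between fitted knots.

    Returns the smallest such diameter when the fit is flat at the
    threshold.  Raises if the threshold lies outside the fitted range.
    """
    d = sweep.table["diameter_um"].to_numpy(dtype=float)
    p = sweep.table["min_pressure_mmHg"].to_numpy(dtype=float)
    fit = isotonic_fit(d, p, direction="decreasing", bounds=PRESSURE_BOUNDS)
    y = fit.y_fit
    if not (y.min() <= threshold <= y.max()):
        raise ValueError(
            f"threshold {threshold} mmHg outside fitted pressure range "
            f"[{y.min():.3g}, {y.max():.3g}]"
        )
    for i in range(len(d) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 >= threshold >= y1:
            if y0 == y1:  # flat at threshold: smallest diameter
                return float(d[i])
            t = (y0 - threshold) / (y0 - y1)
            return float(d[i] + t * (d[i + 1] - d[i]))
    # threshold equals an endpoint value
    idx = int(np.argmin(np.abs(y - threshold)))
    return float(d[idx])


def classify_thresholds(sweep: SweepResult,
                        thresholds: tuple[float, float] = (50.0, 100.0)) -> ThresholdReport:
    """Split the diameter axis into safe (> high threshold), hypoxia-forming
    (between the crossings) and necrotic (below the low-threshold crossing)
    ranges."""
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")

    def safe_crossing(th):
        try:
            return crossing_diameter(sweep, th)
        except ValueError:
            return None

    c_high = safe_crossing(high)
    c_low = safe_crossing(low)
    if c_high is not None and c_low is not None and not c_high < c_low:
        raise ValueError("decreasing sweep must cross the high threshold first")
    forming = (c_high, c_low) if (c_high is not None and c_low is not None) else None
    return ThresholdReport(
        kind=sweep.kind,
        thresholds=(float(low), float(high)),
        crossing_low_um=c_low,
        crossing_high_um=c_high,
        safe_max_um=c_high,
        forming_range_um=forming,
        necrotic_min_um=c_low,
    )


# ---------------------------------------------------------------------------
# early-time linear dynamics


@dataclass(frozen=True)
class LinearFit:
    """OLS line P̂(t) = A + B·t through the first points of a min-pressure
    trajectory (optionally log-transformed)."""

    A: float                 # intercept, mmHg (or log mmHg)
    B: float                 # slope, mmHg/s (or 1/s)
    A_stderr: float
    B_stderr: float
    resid_var: float
    n_points: int
    log_transform: bool = False


def fit_linear_dynamics(ts: TimeSeries, n_points: int = 10,
                        log_transform: bool = False) -> LinearFit:
    """Fit the early, consumption-dominated part of the trajectory.

    Uses the first ``n_points`` output samples.  With ``log_transform`` the
    fit is on log(min pressure); the default fits raw pressures, whose slope
    approaches −OCR while diffusion has not yet reached the deep interior.
    """
    if len(ts.times) < n_points:
        raise ValueError(f"time series has {len(ts.times)} points, need {n_points}")
    if n_points < 2:
        raise ValueError("need at least 2 points for a line")
    t = ts.times[:n_points]
    y = ts.min_pressure[:n_points].astype(float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive pressures")
        y = np.log(y)
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    return LinearFit(
        A=float(res.params[0]),
        B=float(res.params[1]),
        A_stderr=float(res.bse[0]),
        B_stderr=float(res.bse[1]),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        n_points=int(n_points),
        log_transform=bool(log_transform),
    )


# ---------------------------------------------------------------------------
# Gardner-noise influence study


def reference_amplitude(radius: float, surface_fraction: float = 0.1) -> float:
    """Per-factor amplitude whose worst-case surface displacement
    (GARDNER_FACTOR_BOUND·a)³ equals ``surface_fraction``·radius."""
    return (surface_fraction * radius) ** (1.0 / 3.0) / GARDNER_FACTOR_BOUND


def factorial_noise_design(radius: float) -> pd.DataFrame:
    """Default 3×3×3 full factorial: a ∈ {0, a_ref, 2a_ref} with a_ref set
    so the peak surface displacement is ~10% of the radius; q ∈ 2π/R·{1,2,4};
    p ∈ {0, 0.5, 1}."""
    a_ref = reference_amplitude(radius)
    a_lv = [0.0, a_ref, 2.0 * a_ref]
    q_lv = [2 * np.pi / radius, 4 * np.pi / radius, 8 * np.pi / radius]
    p_lv = [0.0, 0.5, 1.0]
    rows = list(itertools.product(a_lv, q_lv, p_lv))
    return pd.DataFrame(rows, columns=["a", "q", "p"])


def random_noise_design(radius: float, n: int, seed: int) -> pd.DataFrame:
    """Seeded uniform design over the same ranges as the factorial."""
    rng = np.random.default_rng(seed)
    a_ref = reference_amplitude(radius)
    return pd.DataFrame({
        "a": rng.uniform(0.0, 2.0 * a_ref, n),
        "q": rng.uniform(2 * np.pi / radius, 8 * np.pi / radius, n),
        "p": rng.uniform(0.0, 1.0, n),
    })


def noise_study(design: pd.DataFrame, radius: float,
                cells_per_radius: int = 12,
                config: SimulationConfig | None = None,
                n_points: int = 10,
                log_transform: bool = False) -> pd.DataFrame:
    """Simulate one noisy spheroid per design row and record the linear
    dynamics coefficients.

    All rows share one voxel grid, sized for the largest amplitude in the
    design, so resolution is held fixed across the study.  Returns the
    design with columns ``A`` and ``B`` appended.
    """
    config = config or SimulationConfig()
    if len(design) < 4:
        raise ValueError("noise study needs at least 4 design points")
    needed_t = n_points * config.output_every
    if config.t_end < needed_t:
        config = replace(config, t_end=needed_t)
    # the fit needs the full n_points trajectory even if the field settles
    # sooner, so the steady early-stop is effectively disabled here
    config = replace(config, steady_tol=1e-15)

    a_max = float(design["a"].max())
    envelope = noisy_spheroid(SpheroidSpec(
        radius=radius, noise=GardnerNoiseParams(a=a_max, q=1.0, p=0.0)))
    grid = GridSpec.for_model(envelope, spacing=radius / cells_per_radius, pad_cells=2)

    out = []
    for row in design.itertuples(index=True):
        params = GardnerNoiseParams(a=float(row.a), q=float(row.q), p=float(row.p))
        model = noisy_spheroid(SpheroidSpec(radius=radius, noise=params))
        try:
            ts, _ = simulate(model, grid, config, store_fields=False)
            fit = fit_linear_dynamics(ts, n_points=n_points, log_transform=log_transform)
        except Exception as exc:
            raise RuntimeError(
                f"noise-study row {row.Index} failed for (a={row.a}, q={row.q}, "
                f"p={row.p}): {exc}"
            ) from exc
        out.append((row.a, row.q, row.p, fit.A, fit.B))
    return pd.DataFrame(out, columns=["a", "q", "p", "A", "B"])


@dataclass(frozen=True)
class OLSReport:
    """Per-predictor t-test of one response (A or B) on (a, q, p) with a
    Bonferroni-adjusted significance threshold."""

    response: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    adjusted_alpha: float
    significant: dict[str, bool]


def ols_test(table: pd.DataFrame, response: str, alpha: float = 0.05,
             n_comparisons: int = 2) -> OLSReport:
    """OLS of the response on (a, q, p) with intercept; a predictor is
    significant iff its two-sided p-value is below alpha / n_comparisons
    (default 0.05 / 2 = 0.025)."""
    if response not in ("A", "B"):
        raise ValueError("response must be 'A' or 'B'")
    if len(table) < 5:
        raise ValueError("need at least 5 rows for the OLS test")
    X = table[["a", "q", "p"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < 4:
        raise ValueError("design is collinear; a, q, p effects are not separable")
    y = table[response].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["a", "q", "p"]
    coeffs = {nm: float(res.params[i + 1]) for i, nm in enumerate(names)}
    pvals = {nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)}
    thr = alpha / n_comparisons
    sig = {nm: bool(pvals[nm] < thr) for nm in names}
    return OLSReport(
        response=response, coefficients=coeffs, p_values=pvals,
        adjusted_alpha=float(thr), significant=sig,
    )


@dataclass(frozen=True)
class ARDFit:
    """Sparse Bayesian linear fit: coefficients on (a, q, p), intercept, and
    the learned per-coefficient precisions (large precision ⇒ pruned)."""

    response: str
    coefficients: dict[str, float]
    intercept: float
    precisions: dict[str, float]


def ard_fit(table: pd.DataFrame, response: str) -> ARDFit:
    """Automatic Relevance Determination regression of the response on
    (a, q, p).  Coefficients of irrelevant predictors are shrunk to ~0 by
    their zero-mean Gaussian priors with learned precisions."""
    if response not in ("A", "B"):
        raise ValueError("response must be 'A' or 'B'")
    if len(table) < 5:
        raise ValueError("need at least 5 rows for the ARD fit")
    X = table[["a", "q", "p"]].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    model = ARDRegression(max_iter=500, tol=1e-6, fit_intercept=True)
    model.fit(X, y)
    names = ["a", "q", "p"]
    coeffs = {nm: float(model.coef_[i]) for i, nm in enumerate(names)}
    prec = {nm: float(model.lambda_[i]) for i, nm in enumerate(names)}
    return ARDFit(
        response=response, coefficients=coeffs,
        intercept=float(model.intercept_), precisions=prec,
    )


# ---------------------------------------------------------------------------
# isotonic regression


@dataclass(frozen=True)
class IsotonicFit:
    """Weighted monotone least-squares fit (pool-adjacent-violators), with
    fitted values clipped to physical pressure bounds."""

    x: np.ndarray
    y_fit: np.ndarray
    weights: np.ndarray
    direction: str
    bounds: tuple[float, float]


def isotonic_fit(x, y, weights=None, direction: str = "increasing",
                 bounds: tuple[float, float] = PRESSURE_BOUNDS) -> IsotonicFit:
    """Monotone least-squares fit of y on x.

    Solves min Σ wᵢ (yᵢ − ŷᵢ)² over vectors ŷ that are monotone in the
    declared direction (pool-adjacent-violators), then clips the fitted
    values to ``bounds``.  x must be strictly increasing after sorting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("isotonic fit requires at least one point")
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    if np.any(np.diff(xs) <= 0):
        raise ValueError("x values must be distinct")
    iso = IsotonicRegression(increasing=(direction == "increasing"),
                             out_of_bounds="clip")
    y_fit = iso.fit_transform(xs, ys, sample_weight=ws)
    y_fit = np.clip(y_fit, bounds[0], bounds[1])
    return IsotonicFit(x=xs, y_fit=y_fit, weights=ws, direction=direction,
                       bounds=(float(bounds[0]), float(bounds[1])))
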