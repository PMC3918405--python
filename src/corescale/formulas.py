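"""Candidate formula families for the CR response surface, model selection,
and inversion at a CR threshold.

Twelve closed-form families relate the sampling percentage ``x`` (percent,
typically 10-30), the trait count ``y`` (1-20) and the expected value of an
evaluation parameter such as CR.  Each family is refit to a simulated
surface by multi-start nonlinear least squares; families are compared by
complexity (fixed expression size), mean absolute error and R^2; the
selected family is then inverted at a CR threshold (conventionally 80) to
give the optimal sampling percentage per trait count.

``log`` is the natural logarithm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = ["FAMILIES", "FormulaFamily", "CandidateFormulaFit", "OptimalCurve",
           "family_surface", "fit_families", "select_formula",
           "invert_at_threshold", "invert_bisection"]

_PENALTY = 1e6
_MIN_LOG_ARG = 1e-12


def _safe_log(arg):
    """log with a smooth, steep penalty below the domain boundary, so the
    optimizer is pushed back rather than fed NaNs."""
    arg = np.asarray(arg, float)
    ok = arg > _MIN_LOG_ARG
    out = np.where(ok, np.log(np.where(ok, arg, 1.0)),
                   np.log(_MIN_LOG_ARG) - _PENALTY * (_MIN_LOG_ARG - arg))
    return out


@dataclass(frozen=True)
class FormulaFamily:
    """One candidate family f(x, y; params).

    ``size`` is the fixed expression complexity used for model selection;
    ``printed_constants`` are reference coefficient values from the
    originating surface fit, used to initialize the optimizer and as frozen
    parameters where a known curve is required.  ``log_args`` returns the
    arguments of every log in the expression (domain constraints).
    """
    family_id: int
    size: int
    expression: str
    param_names: tuple
    printed_constants: tuple
    f: Callable
    log_args: Callable
    reference_error: float
    reference_r2: float
    closed_inverse: Optional[Callable] = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _f1(p, x, y):
    a, b = p
    return a + b * x * y


def _f2(p, x, y):
    a, b = p
    return a + b * _safe_log(x * y)


def _f3(p, x, y):
    a, b, c = p
    return a + b * x + c * _safe_log(x * y)


def _f4(p, x, y):
    a, b, c = p
    return a + b * _safe_log(y) - c / x


def _f5(p, x, y):
    a, b, c = p
    return a + b * _safe_log(x * y - c * y)


def _f6(p, x, y):
    a, b, c, d = p
    return a + b * _safe_log(x * y - c * y - d)


def _f6_inverse(p, z, y):
    a, b, c, d = p
    return (np.exp((z - a) / b) + c * y + d) / y


def _f7(p, x, y):
    a, b, c, d = p
    return a + (y - b) / x + c * _safe_log(x * y - d)


def _f8(p, x, y):
    a, b, c, d, e = p
    return a + b * _safe_log(y) - c / (d + x + e * _safe_log(y))


def _f9(p, x, y):
    a, b, c, d, e = p
    return a + b * y + c * _safe_log(x + x * y) - (d * y + e) / (x + x * y)


def _f10(p, x, y):
    a, b, c, d, e = p
    return a + b * y + c * _safe_log(x * y) - (d * y + e) / (x * y)


def _f11(p, x, y):
    a, b, c, d, e = p
    return a + b * y + c * _safe_log(x * y) - (d * y + e) / (x + y + x * y)


def _f12(p, x, y):
    # the log(xy) coefficient is shared between the two occurrences
    a, b, c, d, e = p
    lg = _safe_log(x * y)
    return a + b * y + c * lg - (d * y + e) / (x + x * y + c * lg)


def _no_log(p, x, y):
    return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, 1.0)


FAMILIES: dict = {}


def _register(family_id, size, expression, names, constants, f, log_args,
              ref_error, ref_r2, closed_inverse=None):
    FAMILIES[family_id] = FormulaFamily(
        family_id=family_id, size=size, expression=expression,
        param_names=tuple(names), printed_constants=tuple(constants),
        f=f, log_args=log_args, reference_error=ref_error,
        reference_r2=ref_r2, closed_inverse=closed_inverse)


_register(1, 7, "a + b*x*y", "ab", (84.24, 0.03), _f1, _no_log,
          0.389, 0.7222)
_register(2, 9, "a + b*log(x*y)", "ab", (59.55, 5.95), _f2,
          lambda p, x, y: x * y, 0.180, 0.9571)
_register(3, 11, "a + b*x + c*log(x*y)", "abc", (70.37, 0.40, 5.46), _f3,
          lambda p, x, y: x * y, 0.161, 0.9619)
_register(4, 12, "a + b*log(y) - c/x", "abc", (85.72, 5.40, 133.68), _f4,
          lambda p, x, y: y, 0.120, 0.9746)
_register(5, 13, "a + b*log(x*y - c*y)", "abc", (64.26, 5.39, 5.02), _f5,
          lambda p, x, y: x * y - p[2] * y, 0.114, 0.9757)
_register(6, 15, "a + b*log(x*y - c*y - d)", "abcd",
          (65.90, 5.12, 5.07, 4.24), _f6,
          lambda p, x, y: x * y - p[2] * y - p[3], 0.090, 0.9896,
          closed_inverse=_f6_inverse)
_register(7, 18, "a + (y - b)/x + c*log(x*y - d)", "abcd",
          (69.88, 61.33, 4.56, 8.75), _f7,
          lambda p, x, y: x * y - p[3], 0.083, 0.9917)
_register(8, 20, "a + b*log(y) - c/(d + x + e*log(y))", "abcde",
          (92.17, 4.16, 291.40, 1.34, 2.90), _f8,
          lambda p, x, y: y, 0.078, 0.9926)
_register(9, 24, "a + b*y + c*log(x + x*y) - (d*y + e)/(x + x*y)", "abcde",
          (70.56, 0.09, 4.38, 29.63, 310.22), _f9,
          lambda p, x, y: x + x * y, 0.076, 0.9932)
_register(10, 26, "a + b*y + c*log(x*y) - (d*y + e)/(x*y)", "abcde",
          (77.94, 0.09, 3.10, 53.22, 323.37), _f10,
          lambda p, x, y: x * y, 0.075, 0.9934)
_register(11, 28, "a + b*y + c*log(x*y) - (d*y + e)/(x + y + x*y)", "abcde",
          (78.65, 0.09, 3.01, 60.77, 345.54), _f11,
          lambda p, x, y: x * y, 0.075, 0.9934)
_register(12, 34,
          "a + b*y + c*log(x*y) - (d*y + e)/(x + x*y + c*log(x*y))", "abcde",
          (81.00, 0.11, 2.63, 62.06, 472.15), _f12,
          lambda p, x, y: x * y, 0.075, 0.9935)


@dataclass(frozen=True)
class CandidateFormulaFit:
    """A family refit to a surface: free parameters, error and R^2."""
    family_id: int
    size: int
    params: tuple
    error: float          # mean absolute error on the fitting data
    rmse: float
    r2: float
    converged: bool
    expression: str
    domain: str

    @property
    def family(self) -> FormulaFamily:
        return FAMILIES[self.family_id]

    def predict(self, x, y):
        return self.family.f(np.asarray(self.params, float),
                             np.asarray(x, float), np.asarray(y, float))

    @classmethod
    def from_constants(cls, family_id: int, params=None) -> "CandidateFormulaFit":
        """A fit object carrying known coefficients (no refitting), e.g.
        the reference constants of a family."""
        fam = FAMILIES[family_id]
        params = fam.printed_constants if params is None else tuple(params)
        return cls(family_id=family_id, size=fam.size, params=tuple(params),
                   error=float("nan"), rmse=float("nan"), r2=float("nan"),
                   converged=True, expression=fam.expression,
                   domain="log arguments must stay positive")


@dataclass(frozen=True)
class OptimalCurve:
    """Optimal sampling percentage per trait count at a fixed CR threshold."""
    cr_star: float
    family_id: int
    params: tuple
    trait_counts: tuple
    percentages: tuple        # x*(y), NaN where undefined
    defined: tuple            # bool per trait count
    notes: tuple              # per trait count: "" | reason / warning

    def rounded(self, ndigits: int = 2):
        return tuple(round(p, ndigits) if d else float("nan")
                     for p, d in zip(self.percentages, self.defined))


def family_surface(family_id: int, params, percentages, trait_counts,
                   noise_sd: float = 0.0, seed: int | None = None):
    """Evaluate a family on a grid, optionally with additive Gaussian noise.

    Returns (X, Y, Z) flattened arrays; the natural input for
    :func:`fit_families` oracle tests."""
    fam = FAMILIES[family_id]
    X, Y = np.meshgrid(np.asarray(percentages, float),
                       np.asarray(trait_counts, float), indexing="xy")
    Z = fam.f(np.asarray(params, float), X, Y)
    if noise_sd:
        rng = np.random.default_rng(seed)
        Z = Z + rng.normal(0.0, noise_sd, size=Z.shape)
    return X.ravel(), Y.ravel(), Z.ravel()


def _surface_xyz(surface):
    cfg = surface.config
    X, Y = np.meshgrid(np.asarray(cfg.percentages, float),
                       np.asarray(cfg.trait_counts, float), indexing="xy")
    return X.ravel(), Y.ravel(), surface.means.ravel()


def _fit_one(fam: FormulaFamily, x, y, z, n_starts: int, seed: int):
    rng = np.random.default_rng(seed)
    p0 = np.asarray(fam.printed_constants, float)
    starts = [p0]
    for scale in (0.9, 1.1):
        starts.append(p0 * scale)
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(p0 * rng.uniform(0.7, 1.3, size=p0.shape))

    def residuals(p):
        return fam.f(p, x, y) - z

    best = None
    for start in starts:
        try:
            sol = optimize.least_squares(residuals, start, method="lm",
                                         max_nfev=20000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if np.any(np.asarray(fam.log_args(sol.x, x, y)) <= _MIN_LOG_ARG):
            continue  # solution violates the log domain on the data
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_families(surface, families: Iterable[int] | None = None,
                 n_starts: int = 8, seed: int = 0):
    """Refit candidate families to a simulated surface.

    ``surface`` is a :class:`~corescale.surface.CRSurface` or an ``(x, y, z)``
    triple of flat arrays.  Families that fail to converge from every start
    are reported with ``converged=False`` rather than raising.  Results are
    sorted by decreasing R^2.
    """
    if isinstance(surface, tuple):
        x, y, z = (np.asarray(v, float) for v in surface)
    else:
        x, y, z = _surface_xyz(surface)
    if families is None:
        families = sorted(FAMILIES)
    fits = []
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    for fid in families:
        fam = FAMILIES[fid]
        if len(z) < fam.n_params:
            raise ValueError(
                f"family {fid} has {fam.n_params} parameters but the "
                f"surface has only {len(z)} cells")
        sol = _fit_one(fam, x, y, z, n_starts, seed + fid)
        if sol is None:
            fits.append(CandidateFormulaFit(
                family_id=fid, size=fam.size, params=fam.printed_constants,
                error=float("inf"), rmse=float("inf"), r2=-float("inf"),
                converged=False, expression=fam.expression,
                domain="log arguments must stay positive"))
            continue
        pred = fam.f(sol.x, x, y)
        resid = pred - z
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        fits.append(CandidateFormulaFit(
            family_id=fid, size=fam.size, params=tuple(float(v) for v in sol.x),
            error=float(np.mean(np.abs(resid))),
            rmse=float(np.sqrt(np.mean(resid ** 2))),
            r2=r2, converged=True, expression=fam.expression,
            domain="log arguments must stay positive"))
    fits.sort(key=lambda f: -f.r2)
    return fits


def select_formula(fits: Sequence[CandidateFormulaFit],
                   r2_floor: float = 0.70,
                   error_tolerance: float = 0.20) -> CandidateFormulaFit:
    """Pick the working formula: drop fits below the R^2 floor, then take
    the smallest-size family whose error is within ``error_tolerance``
    (relative) of the best error.  Ties break toward lower error, then
    lower family id."""
    viable = [f for f in fits if f.converged and f.r2 >= r2_floor]
    if not viable:
        raise ValueError(
            "no candidate formula reaches the R^2 floor; enlarge the grid "
            "or increase replications")
    best_error = min(f.error for f in viable)
    near = [f for f in viable if f.error <= best_error * (1 + error_tolerance)]
    return min(near, key=lambda f: (f.size, f.error, f.family_id))


def invert_bisection(fit: CandidateFormulaFit, cr_star: float, y: float,
                     x_hi: float = 500.0):
    """Solve f(x, y) = cr_star for x by bracketing + Brent's method.

    Returns (x, note) with x = NaN when no root exists in the domain."""
    fam = fit.family
    p = np.asarray(fit.params, float)

    def g(x):
        return float(fam.f(p, np.asarray(x, float), y) - cr_star)

    # establish the domain lower edge by scanning for finite log arguments
    grid = np.linspace(1e-6, x_hi, 4096)
    args = np.asarray(fam.log_args(p, grid, np.full_like(grid, y)), float)
    ok = args > _MIN_LOG_ARG
    if not ok.any():
        return float("nan"), "log domain empty over the search interval"
    xs = grid[ok]
    vals = np.array([g(x) for x in xs])
    signs = np.sign(vals)
    crossings = np.flatnonzero(np.diff(signs) != 0)
    if crossings.size == 0:
        exact = np.flatnonzero(vals == 0)
        if exact.size:
            return float(xs[exact[0]]), ""
        return float("nan"), "no root in the search domain"
    i = crossings[0]
    root = optimize.brentq(g, xs[i], xs[i + 1], xtol=1e-12, rtol=8.9e-16)
    return float(root), ""


def invert_at_threshold(fit: CandidateFormulaFit, cr_star: float,
                        trait_counts: Iterable[int],
                        fitted_percentages: Sequence[float] | None = None
                        ) -> OptimalCurve:
    """Optimal sampling percentage x*(y) with f(x*, y) = cr_star per trait
    count, via the family's closed-form inverse when available, otherwise
    bisection.  Cells whose root leaves the log domain are flagged
    undefined; roots outside the fitted percentage grid get an
    extrapolation note."""
    fam = fit.family
    p = np.asarray(fit.params, float)
    ys = [int(y) for y in trait_counts]
    xs, defined, notes = [], [], []
    for y in ys:
        note = ""
        if fam.closed_inverse is not None:
            x = float(fam.closed_inverse(p, float(cr_star), float(y)))
            if not np.isfinite(x) or x <= 0:
                x, note = float("nan"), "closed-form inverse out of range"
        else:
            x, note = invert_bisection(fit, cr_star, float(y))
        if np.isfinite(x):
            arg = np.min(np.asarray(fam.log_args(p, np.asarray([x]),
                                                 np.asarray([float(y)]))))
            if arg <= _MIN_LOG_ARG:
                x, note = float("nan"), "log argument non-positive at root"
        ok = bool(np.isfinite(x))
        if ok and fitted_percentages is not None and len(fitted_percentages):
            lo, hi = min(fitted_percentages), max(fitted_percentages)
            if not (lo <= x <= hi):
                note = f"extrapolated outside the fitted grid [{lo}, {hi}]"
        xs.append(x if ok else float("nan"))
        defined.append(ok)
        notes.append(note)
    return OptimalCurve(cr_star=float(cr_star), family_id=fit.family_id,
                        params=tuple(fit.params), trait_counts=tuple(ys),
                        percentages=tuple(xs), defined=tuple(defined),
                        notes=tuple(notes))
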