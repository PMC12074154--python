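"""Height–diameter growth models: fitting, selection, and inversion.

Four classical two-parameter height–DBH curves are supported::

    linear        H = a + b·D
    power         H = 1.3 + a·D^b
    logarithmic   H = a + b·ln D
    bates         H = a·D / (b + D)

with H the tree height in meters and D the diameter at breast height in
centimeters.  Models are fitted per species by least squares on field
(H, D) pairs, scored with SSE / RMSE / R² / AIC, the AIC-best form is
selected, and the chosen curve is inverted to predict DBH from
LiDAR-measured heights.

Under Gaussian errors the maximized log-likelihood gives
``AIC = n·ln(SSE/n) + 2k`` up to an additive constant shared by every
candidate, so the reported AIC uses that convention; all four forms have
k = 2 parameters, hence at fixed n the AIC ordering coincides with the
SSE ordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FORM_ORDER",
    "FitMetrics",
    "GrowthModelFit",
    "FitConvergenceError",
    "hd_forward",
    "hd_inverse",
    "compute_metrics",
    "fit_growth_model",
    "fit_all_forms",
    "select_best",
    "predict_dbh",
    "simulate_hd_pairs",
    "save_registry",
    "load_registry",
]

#: Canonical form order; used for deterministic tie-breaking in selection.
FORM_ORDER = ("linear", "power", "logarithmic", "bates")

#: Breast height (m); the power form is anchored at H = 1.3 m as D -> 0.
BREAST_HEIGHT_M = 1.3


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge within the iteration budget."""

    def __init__(self, form: str, residual: float):
        self.form = form
        self.residual = residual
        super().__init__(
            f"{form} fit did not converge (last residual norm {residual:.4g})"
        )


@dataclass
class FitMetrics:
    """Goodness-of-fit summary for a predicted-vs-observed comparison.

    ``r2`` is None (with ``r2_undefined`` set) when the observations have
    zero variance, in which case the coefficient of determination does not
    exist.
    """

    sse: float
    rmse: float
    r2: float | None
    aic: float
    n: int
    k: int
    r2_undefined: bool = False


@dataclass
class GrowthModelFit:
    form: str
    a: float
    b: float
    metrics: FitMetrics
    species: str | None = None


def hd_forward(form: str, a: float, b: float, dbh_cm):
    """Evaluate H(D) for a given form; vectorized over ``dbh_cm``."""
    d = np.asarray(dbh_cm, dtype=float)
    if form == "linear":
        return a + b * d
    if form == "power":
        return BREAST_HEIGHT_M + a * d**b
    if form == "logarithmic":
        return a + b * np.log(d)
    if form == "bates":
        return a * d / (b + d)
    raise ValueError(f"unknown growth-model form {form!r}")


def hd_inverse(form: str, a: float, b: float, height_m):
    """Raw algebraic inverse D(H) of each form (no domain policy applied)."""
    h = np.asarray(height_m, dtype=float)
    if form == "linear":
        return (h - a) / b
    if form == "power":
        return ((h - BREAST_HEIGHT_M) / a) ** (1.0 / b)
    if form == "logarithmic":
        return np.exp((h - a) / b)
    if form == "bates":
        return b * h / (a - h)
    raise ValueError(f"unknown growth-model form {form!r}")


def compute_metrics(pred, obs, k: int) -> FitMetrics:
    """SSE, RMSE, R² and AIC between predictions and observations.

    SSE = Σ(P−O)²; RMSE = √(SSE/n); R² = 1 − SSE/Σ(O−Q)² with Q the mean
    of the observations; AIC = n·ln(SSE/n) + 2k (Gaussian, additive
    constant dropped).
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sse = float(np.sum((p - o) ** 2))
    rmse = math.sqrt(sse / n)
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0.0:
        r2, undefined = None, True
    else:
        r2, undefined = 1.0 - sse / tss, False
    aic = (n * math.log(sse / n) if sse > 0 else -math.inf) + 2 * k
    return FitMetrics(sse=sse, rmse=rmse, r2=r2, aic=aic, n=n, k=k,
                      r2_undefined=undefined)


def _fit_linear_in_basis(x, h):
    # closed-form simple linear regression of h on basis x
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, h, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_growth_model(form: str, dbh_cm, height_m,
                     species: str | None = None) -> GrowthModelFit:
    """Least-squares fit of one height–DBH form.

    Linear and logarithmic forms are solved in closed form; power and
    Bates by bounded-iteration nonlinear least squares from fixed starting
    values (power: a=1, b=0.5; Bates: a=1.1·max H, b=median D).
    """
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if d.size != h.size:
        raise ValueError("dbh and height must have equal length")
    if d.size < 3:
        raise ValueError(f"need at least 3 pairs, got {d.size}")
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("all DBH and height values must be positive")

    if form == "linear":
        a, b = _fit_linear_in_basis(d, h)
    elif form == "logarithmic":
        a, b = _fit_linear_in_basis(np.log(d), h)
    elif form in ("power", "bates"):
        if form == "power":
            x0 = (1.0, 0.5)
            resid = lambda p: BREAST_HEIGHT_M + p[0] * d ** p[1] - h
        else:
            x0 = (1.1 * float(h.max()), float(np.median(d)))
            resid = lambda p: p[0] * d / (p[1] + d) - h
        sol = least_squares(resid, x0, max_nfev=500)
        if not sol.success:
            raise FitConvergenceError(form, float(np.linalg.norm(sol.fun)))
        a, b = float(sol.x[0]), float(sol.x[1])
    else:
        raise ValueError(f"unknown growth-model form {form!r}")

    metrics = compute_metrics(hd_forward(form, a, b, d), h, k=2)
    return GrowthModelFit(form=form, a=a, b=b, metrics=metrics, species=species)


def fit_all_forms(dbh_cm, height_m, species: str | None = None):
    """Fit every form in ``FORM_ORDER``; skip non-convergent ones."""
    fits = []
    for form in FORM_ORDER:
        try:
            fits.append(fit_growth_model(form, dbh_cm, height_m, species))
        except FitConvergenceError:
            continue
    return fits


def select_best(fits) -> GrowthModelFit:
    """Minimal-AIC fit; ties broken by higher R², then by form order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no converged fits to select from")

    def key(fit: GrowthModelFit):
        r2 = fit.metrics.r2 if fit.metrics.r2 is not None else -math.inf
        return (fit.metrics.aic, -r2, FORM_ORDER.index(fit.form))

    return min(fits, key=key)


#: Heights this close (fractionally) under a Bates asymptote are clamped
#: to the inverse evaluated at asymptote·(1 − BATES_CLAMP_FRAC).
BATES_CLAMP_FRAC = 0.005


def predict_dbh(fit: GrowthModelFit, height_m):
    """Invert the fitted curve to predict DBH (cm) from height (m).

    Heights outside a form's invertible domain cannot yield a physical
    diameter: those records come back as NaN and are counted in the
    returned flag total.  For the Bates form, heights within 0.5% below
    the asymptote ``a`` are clamped to the capped inverse rather than
    extrapolated to unbounded diameters.

    Returns ``(dbh_cm, n_flagged)``; scalar input gives scalar output.
    """
    h = np.atleast_1d(np.asarray(height_m, dtype=float))
    if np.any(h <= 0):
        raise ValueError("heights must be positive")
    dbh = np.full(h.shape, np.nan)
    a, b, form = fit.a, fit.b, fit.form

    if form == "bates":
        cap = a * (1.0 - BATES_CLAMP_FRAC)
        ok = h < cap
        clamp = (h >= cap) & (h < a)
        dbh[ok] = hd_inverse(form, a, b, h[ok])
        dbh[clamp] = hd_inverse(form, a, b, cap)
    elif form == "power":
        ok = h > BREAST_HEIGHT_M
        dbh[ok] = hd_inverse(form, a, b, h[ok])
    else:
        dbh[:] = hd_inverse(form, a, b, h)

    dbh[~np.isnan(dbh) & (dbh <= 0)] = np.nan
    n_flagged = int(np.isnan(dbh).sum())
    if np.isscalar(height_m) or np.ndim(height_m) == 0:
        return float(dbh[0]), n_flagged
    return dbh, n_flagged


def anchored_params(form: str, p1: tuple[float, float],
                    p2: tuple[float, float]) -> tuple[float, float]:
    """(a, b) such that the form passes through (D1, H1) and (D2, H2).

    Anchoring every form to the same stand envelope (e.g. the smallest and
    largest tree of a plantation) yields four curves that describe the same
    stands but differ in shape, which is the clean setting for comparing
    model-selection behavior across forms.
    """
    (d1, h1), (d2, h2) = p1, p2
    if form == "linear":
        b = (h2 - h1) / (d2 - d1)
        return h1 - b * d1, b
    if form == "logarithmic":
        b = (h2 - h1) / math.log(d2 / d1)
        return h1 - b * math.log(d1), b
    if form == "power":
        b = math.log((h2 - BREAST_HEIGHT_M) / (h1 - BREAST_HEIGHT_M)) \
            / math.log(d2 / d1)
        return (h1 - BREAST_HEIGHT_M) / d1**b, b
    if form == "bates":
        b = d1 * d2 * (h1 - h2) / (h2 * d1 - h1 * d2)
        return h1 * (b + d1) / d1, b
    raise ValueError(f"unknown growth-model form {form!r}")


def simulate_hd_pairs(form: str, a: float, b: float, n: int,
                      d_range: tuple[float, float], noise_sd_m: float,
                      rng: np.random.Generator):
    """Draw (D, H) field pairs from a known growth curve plus height noise.

    Diameters are uniform over ``d_range``; heights are the exact curve
    value plus N(0, noise_sd_m²), truncated below at 0.5 m so the pairs
    stay physically admissible.
    """
    d = rng.uniform(*d_range, size=n)
    h = hd_forward(form, a, b, d) + rng.normal(0.0, noise_sd_m, size=n)
    return d, np.maximum(h, 0.5)


def save_registry(fits, path) -> None:
    """Write a species → fitted-model JSON registry."""
    reg = {}
    for fit in fits:
        if fit.species is None:
            raise ValueError("registry entries need a species label")
        reg[fit.species] = {
            "form": fit.form, "a": fit.a, "b": fit.b,
            "metrics": asdict(fit.metrics),
        }
    Path(path).write_text(json.dumps(reg, indent=2))


def load_registry(path) -> dict[str, GrowthModelFit]:
    reg = json.loads(Path(path).read_text())
    out = {}
    for species, entry in reg.items():
        out[species] = GrowthModelFit(
            form=entry["form"], a=entry["a"], b=entry["b"],
            metrics=FitMetrics(**entry["metrics"]), species=species,
        )
    return out
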