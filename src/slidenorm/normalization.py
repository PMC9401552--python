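"""Intensity transforms and slide-effect removal.

Two layers are applied in sequence to the marker columns, mirroring the
two-argument normalization call of the workflow:

* a **transform** — an elementwise or per-slide rescaling
  (``"None"``, ``"log10"``, ``"mean_divide"``, ``"log10_mean_divide"``);
* a **method** — a model-based batch correction (``"None"`` or ``"ComBat"``),
  or a user-supplied normalizer function.

The ComBat implementation follows the parametric empirical-Bayes
location/scale model: per marker, slide effects are estimated by least
squares, residuals standardized by the pooled variance, normal (location)
and inverse-gamma (scale) priors fitted per slide by method of moments
across markers, and posterior slide effects obtained by iterating the
conditional posterior updates to convergence. Slides are the sole batch variable; no covariates
are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import MxDataset, validate_normalized

__all__ = [
    "TRANSFORMS",
    "METHODS",
    "transform_log10",
    "transform_mean_divide",
    "transform_log10_mean_divide",
    "CombatModel",
    "fit_combat",
    "apply_combat",
    "normalize",
    "RegistryError",
    "DegenerateGroupError",
    "InsufficientBatchesError",
    "ContractViolationError",
]


class RegistryError(ValueError):
    """Unknown transform or method name."""


class DegenerateGroupError(ValueError):
    """A (slide, marker) group is degenerate for the requested operation."""


class InsufficientBatchesError(ValueError):
    """ComBat requires at least two slides."""


class ContractViolationError(ValueError):
    """A user-supplied normalizer returned a table violating the shape contract."""


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform_log10(values) -> np.ndarray:
    """Elementwise ``log10(y + 1)``; the +1 offset keeps exact zeros finite."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log10 transform requires nonnegative values")
    return np.log10(arr + 1.0)


def _slide_marker_means(table: pd.DataFrame, marker_cols, slide_id) -> pd.DataFrame:
    means = table.groupby(slide_id, observed=True)[list(marker_cols)].mean()
    for marker in marker_cols:
        zero = means.index[means[marker] <= 0]
        if len(zero):
            raise DegenerateGroupError(
                f"marker {marker!r} has mean <= 0 on slide(s) {zero.tolist()}; "
                "mean_divide is undefined there"
            )
    return means


def transform_mean_divide(table: pd.DataFrame, marker_cols, slide_id) -> pd.DataFrame:
    """Divide each marker value by that marker's mean on its own slide.

    After the transform every (slide, marker) group has mean exactly 1, so
    multiplicative slide effects are removed by construction.
    """
    means = _slide_marker_means(table, marker_cols, slide_id)
    out = table.copy()
    denom = means.loc[table[slide_id]].to_numpy()
    out[list(marker_cols)] = table[list(marker_cols)].to_numpy() / denom
    return out


def transform_log10_mean_divide(table: pd.DataFrame, marker_cols, slide_id) -> pd.DataFrame:
    """``log10(y / slide-marker mean + 1)`` — mean_divide followed by log10."""
    out = transform_mean_divide(table, marker_cols, slide_id)
    out[list(marker_cols)] = np.log10(out[list(marker_cols)].to_numpy() + 1.0)
    return out


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

@dataclass
class CombatModel:
    """Fitted empirical-Bayes location/scale model with slide as batch.

    ``gamma_star`` / ``delta_star_sq`` are posterior per-(slide, marker)
    location shifts and variance scale factors on the standardized scale;
    ``grand_mean`` and ``pooled_var`` restore the original marker scale.
    Prior hyperparameters are per slide: the empirical-Bayes step pools
    the least-squares batch effects across markers within each slide.
    """

    marker_cols: list[str]
    slides: list[str]
    grand_mean: pd.Series          # alpha_m
    pooled_var: pd.Series          # sigma^2_m
    gamma_hat: pd.DataFrame        # slides x markers, LS estimates
    delta_hat_sq: pd.DataFrame
    gamma_star: pd.DataFrame       # slides x markers, posterior
    delta_star_sq: pd.DataFrame
    gamma_bar: pd.Series           # per-slide location prior mean
    tau_sq: pd.Series              # per-slide location prior variance
    a_prior: pd.Series             # per-slide inverse-gamma shape (lambda)
    b_prior: pd.Series             # per-slide inverse-gamma rate (theta)
    n_iter: dict[str, int] | None = None


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def fit_combat(
    table: pd.DataFrame,
    marker_cols: Sequence[str],
    slide_id: str,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CombatModel:
    """Fit the parametric empirical-Bayes batch model with one batch per slide.

    Per marker, slide effects are estimated by least squares and residuals
    standardized by the pooled within-slide variance. Normal (location) and
    inverse-gamma (scale) priors are then fitted per slide by method of
    moments across markers, and posterior effects obtained by iterating the
    conditional posterior-mean/variance updates to convergence.
    """
    marker_cols = list(marker_cols)
    if len(marker_cols) < 2:
        raise DegenerateGroupError(
            "ComBat pools its empirical-Bayes priors across markers; "
            "at least 2 marker columns are required"
        )
    groups = table.groupby(slide_id, observed=True)
    slides = list(groups.groups)
    if len(slides) < 2:
        raise InsufficientBatchesError(
            f"ComBat requires at least 2 slides, found {len(slides)}"
        )
    sizes = groups.size()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise InsufficientBatchesError(f"slides with fewer than 2 cells: {small}")

    y = table[marker_cols].to_numpy(dtype=float)
    n_total = len(table)
    batch_means = groups[marker_cols].mean()          # slides x markers
    n_per = sizes.to_numpy()[:, None]

    # weighted grand mean and pooled residual variance (divide by N) from the
    # least-squares fit with batch indicators
    grand_mean = pd.Series(
        (batch_means.to_numpy() * n_per).sum(axis=0) / n_total, index=marker_cols
    )
    fitted = batch_means.loc[table[slide_id]].to_numpy()
    resid = y - fitted
    pooled_var = pd.Series((resid ** 2).sum(axis=0) / n_total, index=marker_cols)
    if (pooled_var <= 0).any():
        bad = pooled_var.index[pooled_var <= 0].tolist()
        raise DegenerateGroupError(
            f"markers with zero pooled within-slide variance: {bad}"
        )

    z = (y - grand_mean.to_numpy()) / np.sqrt(pooled_var.to_numpy())
    zdf = pd.DataFrame(z, columns=marker_cols)
    zdf[slide_id] = table[slide_id].to_numpy()
    zgroups = zdf.groupby(slide_id, observed=True)
    gamma_hat = zgroups[marker_cols].mean().loc[slides]
    delta_hat_sq = zgroups[marker_cols].var(ddof=1).loc[slides]

    # method-of-moments priors per slide, pooled across markers
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    d_bar = delta_hat_sq.mean(axis=1)
    d_s2 = delta_hat_sq.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2.0 * d_s2 + d_bar ** 2) / d_s2
        b_prior = (d_bar * d_s2 + d_bar ** 3) / d_s2

    gamma_star = gamma_hat.copy()
    delta_star_sq = delta_hat_sq.copy()
    n_iter: dict[str, int] = {}
    for s in slides:
        idx = zdf[slide_id].to_numpy() == s
        zs = z[idx]
        n_s = zs.shape[0]
        g_hat = gamma_hat.loc[s].to_numpy()
        g_old = g_hat.copy()
        d_old = delta_hat_sq.loc[s].to_numpy()
        g_bar = float(gamma_bar.loc[s])
        t2 = float(tau_sq.loc[s])
        a = float(a_prior.loc[s])
        b = float(b_prior.loc[s])
        # degenerate priors (markers behave identically): keep the LS estimates
        usable = np.isfinite(a) and np.isfinite(b) and t2 > 0
        count = 0
        while usable and count < max_iter:
            g_new = _postmean(g_hat, g_bar, n_s, d_old, t2)
            ssq = ((zs - g_new) ** 2).sum(axis=0)
            d_new = _postvar(ssq, n_s, a, b)
            count += 1
            change = np.max(
                np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)
            )
            change = max(
                change,
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star.loc[s] = g_old
        delta_star_sq.loc[s] = d_old
        n_iter[s] = count

    if (delta_star_sq.to_numpy() <= 0).any():
        raise DegenerateGroupError("ComBat produced a nonpositive posterior scale")

    return CombatModel(
        marker_cols=marker_cols,
        slides=[str(s) for s in slides],
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_hat=gamma_hat,
        delta_hat_sq=delta_hat_sq,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=n_iter,
    )


def apply_combat(table: pd.DataFrame, model: CombatModel, slide_id: str) -> pd.DataFrame:
    """Remove fitted slide effects: ``y* = sigma_m/delta*_sm (z - gamma*_sm) + alpha_m``."""
    seen = set(model.gamma_star.index.astype(str))
    present = set(table[slide_id].astype(str).unique())
    unseen = sorted(present - seen)
    if unseen:
        raise ValueError(f"slides not present in the fitted ComBat model: {unseen}")

    markers = model.marker_cols
    y = table[markers].to_numpy(dtype=float)
    sigma = np.sqrt(model.pooled_var.to_numpy())
    z = (y - model.grand_mean.to_numpy()) / sigma
    g = model.gamma_star.loc[table[slide_id]].to_numpy()
    d = np.sqrt(model.delta_star_sq.loc[table[slide_id]].to_numpy())
    adjusted = sigma * (z - g) / d + model.grand_mean.to_numpy()
    out = table.copy()
    out[markers] = adjusted
    return out


# ---------------------------------------------------------------------------
# registry + driver
# ---------------------------------------------------------------------------

def _apply_transform(name, table, marker_cols, slide_id):
    if name == "None":
        return table.copy()
    if name == "log10":
        out = table.copy()
        out[list(marker_cols)] = transform_log10(table[list(marker_cols)].to_numpy())
        return out
    if name == "mean_divide":
        return transform_mean_divide(table, marker_cols, slide_id)
    if name == "log10_mean_divide":
        return transform_log10_mean_divide(table, marker_cols, slide_id)
    raise AssertionError(name)


TRANSFORMS = ("None", "log10", "mean_divide", "log10_mean_divide")
METHODS = ("None", "ComBat")

UserNormalizer = Callable[..., pd.DataFrame]


def normalize(
    dataset: MxDataset,
    transform: str = "None",
    method: str | UserNormalizer = "None",
    method_params: Optional[Mapping] = None,
) -> MxDataset:
    """Produce the normalized table ``method(transform(raw))`` and record provenance.

    ``method`` may be a callable implementing the user-normalizer contract:
    it receives ``(table, marker_cols, slide_id, image_id, **method_params)``
    and must return a table with unchanged ids, metadata, row count and row
    order; the engine re-validates its output.
    """
    if transform not in TRANSFORMS:
        raise RegistryError(
            f"unknown transform {transform!r}; valid transforms: {list(TRANSFORMS)}"
        )
    user_fn = None
    if callable(method):
        user_fn = method
        method_name = getattr(method, "__name__", "user_defined")
    else:
        if method not in METHODS:
            raise RegistryError(
                f"unknown method {method!r}; valid methods: {list(METHODS)} "
                "or a callable user normalizer"
            )
        method_name = method

    work = _apply_transform(transform, dataset.data, dataset.marker_cols, dataset.slide_id)

    if user_fn is not None:
        params = dict(method_params or {})
        result = user_fn(
            work, list(dataset.marker_cols), dataset.slide_id, dataset.image_id, **params
        )
        if not isinstance(result, pd.DataFrame):
            raise ContractViolationError(
                f"user normalizer returned {type(result).__name__}, expected a DataFrame"
            )
        try:
            work = validate_normalized(dataset, result)
        except ValueError as exc:
            raise ContractViolationError(f"user normalizer output invalid: {exc}") from exc
    elif method_name == "ComBat":
        params = dict(method_params or {})
        model = fit_combat(work, dataset.marker_cols, dataset.slide_id, **params)
        work = apply_combat(work, model, dataset.slide_id)

    norm = validate_normalized(dataset, work)
    return dataset.with_(norm_data=norm, transform=transform, method=method_name)
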