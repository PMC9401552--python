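"""Diagnostics quantifying slide-to-slide technical variation.

Three complementary analyses compare the raw and normalized tables:

* **Otsu threshold discordance** — for each marker, the proportion of cells
  whose positive/negative call flips between a slide-specific Otsu threshold
  and the marker-wide (global) threshold. Residual slide effects move the
  slide thresholds away from the global one and inflate discordance.
* **UMAP embedding** — a seeded 2-D embedding of the marker intensities;
  slide-wise mixing indicates removed batch structure.
* **Variance proportions** — per marker, the share of total variance
  attributable to a slide-level random intercept, estimated by REML.

`summarize_dataset` collects these together with a k-sample
Anderson–Darling statistic of distribution homogeneity across slides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core_data import MxDataset

__all__ = [
    "otsu_threshold",
    "run_otsu_discordance",
    "run_reduce_umap",
    "run_var_proportions",
    "summarize_dataset",
    "SummaryReport",
    "DegenerateInputError",
    "MissingAnalysisError",
    "ConvergenceError",
    "InsufficientGroupsError",
]


class DegenerateInputError(ValueError):
    """Thresholding requested on a constant vector."""


class MissingAnalysisError(ValueError):
    """A result table was requested before its analysis was run."""


class ConvergenceError(RuntimeError):
    """The mixed-model fit failed to converge."""


class InsufficientGroupsError(ValueError):
    """An analysis requires more slides than the data contain."""


# ---------------------------------------------------------------------------
# Otsu thresholding + discordance
# ---------------------------------------------------------------------------

def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The observed range is split into ``n_bins`` equal-width bins and each
    internal bin edge is scored by the between-class variance
    ``w0*w1*(mu0-mu1)**2`` of the exact two-class split ``y <= t`` vs
    ``y > t``. The edge with the largest score is returned; ties go to the
    smallest edge, making the result deterministic.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.min(v) == np.max(v):
        raise DegenerateInputError(
            "cannot threshold a constant (or near-empty) vector"
        )
    edges = np.linspace(np.min(v), np.max(v), n_bins + 1)
    candidates = edges[1:-1]
    vs = np.sort(v)
    csum = np.concatenate(([0.0], np.cumsum(vs)))
    n = vs.size
    # strict split: class 0 is y <= t, class 1 is y > t
    n0 = np.searchsorted(vs, candidates, side="right")
    n1 = n - n0
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[n0] / n0
        mu1 = (csum[n] - csum[n0]) / n1
        score = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    score[~valid] = -np.inf
    if not np.isfinite(score).any():
        raise DegenerateInputError("no bin edge splits the data into two classes")
    return float(candidates[int(np.argmax(score))])


def run_otsu_discordance(
    dataset: MxDataset,
    table: str = "both",
    threshold_override: Optional[Callable[[np.ndarray], float]] = None,
    n_bins: int = 256,
) -> MxDataset:
    """Attach per-(table, slide, marker) threshold discordance.

    For each marker a global threshold is computed on the pooled values and a
    slide threshold on each slide's values; the discordance is the fraction
    of the slide's cells whose call ``y > threshold`` differs between the
    two. ``threshold_override`` (a ``values -> threshold`` function) replaces
    the built-in Otsu everywhere, supporting user-defined thresholding.
    """
    thresher = threshold_override or (lambda v: otsu_threshold(v, n_bins=n_bins))
    rows = []
    for tab in dataset.resolve_tables(table):
        df = dataset.table(tab)
        for marker in dataset.marker_cols:
            pooled = df[marker].to_numpy(dtype=float)
            try:
                t_global = float(thresher(pooled))
            except DegenerateInputError as exc:
                raise DegenerateInputError(
                    f"global threshold failed for marker {marker!r} ({tab}): {exc}"
                ) from exc
            for slide, grp in df.groupby(dataset.slide_id, observed=True):
                v = grp[marker].to_numpy(dtype=float)
                try:
                    t_slide = float(thresher(v))
                except DegenerateInputError as exc:
                    raise DegenerateInputError(
                        f"slide threshold failed for slide {slide!r}, marker {marker!r} "
                        f"({tab}): {exc}"
                    ) from exc
                disc = float(np.mean((v > t_slide) != (v > t_global)))
                rows.append(
                    {
                        "table": tab,
                        "slide_id": str(slide),
                        "marker": marker,
                        "slide_threshold": t_slide,
                        "global_threshold": t_global,
                        "discordance": disc,
                        "n_cells": len(v),
                    }
                )
    return dataset.with_(discordance=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# UMAP embedding
# ---------------------------------------------------------------------------

def run_reduce_umap(
    dataset: MxDataset,
    table: str = "both",
    marker_list: Optional[Sequence[str]] = None,
    downsample_pct: float = 1.0,
    metadata_cols: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> MxDataset:
    """Attach a seeded 2-D UMAP embedding of the selected marker columns.

    Cells are downsampled without replacement to ``floor(downsample_pct*n)``
    (the same cells for every table so raw and normalized embeddings are
    comparable). A fixed ``seed`` makes the embedding single-threaded and
    reproducible.
    """
    import umap  # deferred: numba compilation is slow at import time

    marker_list = list(marker_list) if marker_list else []
    if not marker_list:
        raise ValueError("marker_list must name at least one marker column")
    unknown = [m for m in marker_list if m not in dataset.marker_cols]
    if unknown:
        raise ValueError(f"marker_list entries not in dataset markers: {unknown}")
    metadata_cols = list(metadata_cols) if metadata_cols else []
    unknown = [m for m in metadata_cols if m not in dataset.metadata_cols]
    if unknown:
        raise ValueError(f"metadata_cols entries not in dataset metadata: {unknown}")

    tables = dataset.resolve_tables(table)
    n = len(dataset.data)
    k = int(np.floor(downsample_pct * n))
    if k < 10:
        raise ValueError(
            f"downsampling to {k} cells is too few for an embedding (need >= 10)"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))

    frames = []
    for tab in tables:
        df = dataset.table(tab).iloc[idx]
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = reducer.fit_transform(df[marker_list].to_numpy(dtype=float))
        out = pd.DataFrame(
            {
                "table": tab,
                "slide_id": df[dataset.slide_id].to_numpy(),
                "image_id": df[dataset.image_id].to_numpy(),
                "u1": emb[:, 0],
                "u2": emb[:, 1],
            }
        )
        for col in metadata_cols:
            out[col] = df[col].to_numpy()
        frames.append(out)
    return dataset.with_(umap=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# variance proportions (random-intercept REML)
# ---------------------------------------------------------------------------

def run_var_proportions(
    dataset: MxDataset,
    table: str = "both",
    metadata_cols: Optional[Sequence[str]] = None,
    formula_override: Optional[str] = None,
) -> MxDataset:
    """Attach the slide-level share of each marker's variance.

    Per marker, a random-intercept model
    ``value ~ 1 [+ metadata fixed effects] + (1 | slide)`` is fitted by REML
    and the intraclass proportion ``sigma2_slide / (sigma2_slide +
    sigma2_resid)`` reported, together with its complement.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    metadata_cols = list(metadata_cols) if metadata_cols else []
    unknown = [m for m in metadata_cols if m not in dataset.metadata_cols]
    if unknown:
        raise ValueError(f"metadata_cols entries not in dataset metadata: {unknown}")

    rows = []
    for tab in dataset.resolve_tables(table):
        df = dataset.table(tab)
        if df[dataset.slide_id].nunique() < 2:
            raise InsufficientGroupsError(
                "variance proportions require at least 2 slides"
            )
        for marker in dataset.marker_cols:
            work = df[[dataset.slide_id, marker, *metadata_cols]].copy()
            work = work.rename(columns={marker: "value"})
            if formula_override is not None:
                formula = formula_override
            elif metadata_cols:
                formula = "value ~ 1 + " + " + ".join(metadata_cols)
            else:
                formula = "value ~ 1"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                try:
                    fit = smf.mixedlm(
                        formula, work, groups=work[dataset.slide_id]
                    ).fit(reml=True)
                except Exception as exc:  # singular fits, optimizer failures
                    raise ConvergenceError(
                        f"REML fit failed for marker {marker!r} ({tab}): {exc}"
                    ) from exc
            var_slide = float(fit.cov_re.iloc[0, 0])
            var_resid = float(fit.scale)
            total = var_slide + var_resid
            if not np.isfinite(total) or total <= 0:
                raise ConvergenceError(
                    f"REML fit degenerate for marker {marker!r} ({tab})"
                )
            p_slide = var_slide / total
            rows.append(
                {"table": tab, "marker": marker, "level": "slide", "proportion": p_slide}
            )
            rows.append(
                {
                    "table": tab,
                    "marker": marker,
                    "level": "residual",
                    "proportion": 1.0 - p_slide,
                }
            )
    return dataset.with_(var_props=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    """Per-(table, marker) diagnostics plus per-table aggregates.

    ``by_marker`` always carries the Anderson–Darling homogeneity statistic;
    discordance and variance-proportion columns are present only when those
    analyses were run. ``aggregate`` averages each diagnostic over markers
    per table and, when both tables were analyzed, their raw-minus-normalized
    difference appears in ``deltas``.
    """

    by_marker: pd.DataFrame
    aggregate: pd.DataFrame
    deltas: Optional[pd.Series] = None

    def to_text(self) -> str:
        lines = ["Per-marker diagnostics", "----------------------"]
        lines.append(self.by_marker.to_string(index=False, float_format="%.4f"))
        lines += ["", "Per-table aggregates (mean over markers)", "-" * 40]
        lines.append(self.aggregate.to_string(index=False, float_format="%.4f"))
        if self.deltas is not None:
            lines += ["", "Raw minus normalized (positive = improvement)", "-" * 45]
            lines.append(self.deltas.to_string(float_format="%.4f"))
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        self.by_marker.to_csv(path, index=False)


def _ad_statistic(groups: list[np.ndarray]) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.anderson_ksamp(groups)
    return float(res.statistic)


def summarize_dataset(dataset: MxDataset) -> SummaryReport:
    """Build the summary report from whichever analyses have been run."""
    tables = ["raw"] + (["normalized"] if dataset.norm_data is not None else [])
    rows = []
    for tab in tables:
        df = dataset.table(tab)
        for marker in dataset.marker_cols:
            groups = [
                g.to_numpy(dtype=float)
                for _, g in df.groupby(dataset.slide_id, observed=True)[marker]
            ]
            row = {"table": tab, "marker": marker}
            if len(groups) >= 2:
                row["ad_statistic"] = _ad_statistic(groups)
            else:
                row["ad_statistic"] = np.nan
            rows.append(row)
    by_marker = pd.DataFrame(rows)

    if dataset.discordance is not None:
        disc = (
            dataset.discordance.groupby(["table", "marker"])["discordance"]
            .agg(mean_discordance="mean", sd_discordance="std")
            .reset_index()
        )
        by_marker = by_marker.merge(disc, on=["table", "marker"], how="left")
    if dataset.var_props is not None:
        vp = dataset.var_props
        slide_share = vp[vp["level"] == "slide"][["table", "marker", "proportion"]]
        slide_share = slide_share.rename(columns={"proportion": "proportion_slide"})
        by_marker = by_marker.merge(slide_share, on=["table", "marker"], how="left")

    metric_cols = [c for c in by_marker.columns if c not in ("table", "marker", "sd_discordance")]
    aggregate = by_marker.groupby("table", sort=False)[metric_cols].mean().reset_index()

    deltas = None
    if dataset.norm_data is not None:
        agg = aggregate.set_index("table")
        if {"raw", "normalized"} <= set(agg.index):
            deltas = agg.loc["raw"] - agg.loc["normalized"]
    return SummaryReport(by_marker=by_marker, aggregate=aggregate, deltas=deltas)
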