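"""Synthetic cell tables with controllable slide-level batch effects.

The generator emulates segmented single-cell intensity data from a
multi-slide multiplexed-imaging experiment: cells nest in images, images
nest in slides, and each marker's log-intensity follows a two-component
(negative/positive cell) Gaussian mixture, exponentiated to nonnegative,
right-skewed raw intensities. Slide effects are drawn per (slide, marker)
and injected in one of three canonical ways:

* ``"multiplicative"`` — a shift on the log scale, i.e. every intensity on
  the slide is multiplied by a common factor (staining/exposure gain);
  removed exactly by ``mean_divide``.
* ``"additive"`` — a shift on the raw intensity scale (background offset);
  clipped at zero so intensities stay nonnegative.
* ``"scale"`` — the within-slide log-intensity noise SD is multiplied by
  ``exp(u)`` (slide-dependent spread); the target of ComBat's scale
  correction.

Column names mirror the long-format schema the pipeline expects:
``slide_id``, ``image_id``, ``marker{k}_vals``, ``metadata{j}_vals``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import MxDataset, create_dataset

__all__ = ["SimConfig", "simulate_cells", "simulate_dataset"]

SLIDE_EFFECT_TYPES = ("none", "additive", "multiplicative", "scale")


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults mirror a small multi-slide experiment: 4 slides x 3 images x
    250 cells (3000 cells total), 3 markers and 1 metadata column. The
    mixture defaults (30% positive cells, component means 3 noise-SDs apart,
    log-scale noise SD 0.5) give clearly bimodal intensities — the regime
    Otsu thresholding presupposes.
    """

    n_slides: int = 4
    n_images_per_slide: int = 3
    n_cells_per_image: int = 250
    n_markers: int = 3
    n_metadata: int = 1
    slide_effect_type: str = "none"
    slide_effect_sd: float = 0.0
    positive_fraction: float | Sequence[float] = 0.3
    mixture_separation: float = 3.0
    noise_sd: float = 0.5
    base_log_mean: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_slides", "n_images_per_slide", "n_cells_per_image", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_metadata < 0:
            raise ValueError("n_metadata must be >= 0")
        if self.slide_effect_type not in SLIDE_EFFECT_TYPES:
            raise ValueError(
                f"slide_effect_type must be one of {SLIDE_EFFECT_TYPES}, "
                f"got {self.slide_effect_type!r}"
            )
        if self.slide_effect_sd < 0:
            raise ValueError("slide_effect_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mixture_separation <= 0:
            raise ValueError("mixture_separation must be > 0")
        for p in np.atleast_1d(np.asarray(self.positive_fraction, dtype=float)):
            if not (0.0 < p < 1.0):
                raise ValueError(f"positive_fraction must lie in (0, 1), got {p}")

    @property
    def positive_fractions(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.positive_fraction, dtype=float))
        if p.size == 1:
            return np.repeat(p, self.n_markers)
        if p.size != self.n_markers:
            raise ValueError(
                f"positive_fraction has {p.size} entries for {self.n_markers} markers"
            )
        return p


def simulate_cells(config: SimConfig) -> pd.DataFrame:
    """Draw a cell table from the hierarchical log-normal mixture model.

    Fully reproducible from ``config.seed``. Per marker ``m`` and cell ``i``
    on slide ``s``: a positivity label ``z ~ Bernoulli(p_m)``, then

    ``log y = mu_m + z * separation * noise_sd + [u_sm] + sigma_s * eps``

    with ``u_sm ~ N(0, slide_effect_sd^2)`` entering on the log scale
    (multiplicative), on the raw scale after exponentiation (additive), or
    as ``sigma_s = noise_sd * exp(u_sm)`` (scale).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells = config.n_slides * config.n_images_per_slide * config.n_cells_per_image
    slides = np.repeat(
        [f"slide{s + 1}" for s in range(config.n_slides)],
        config.n_images_per_slide * config.n_cells_per_image,
    )
    images = np.repeat(
        [
            f"slide{s + 1}_image{v + 1}"
            for s in range(config.n_slides)
            for v in range(config.n_images_per_slide)
        ],
        config.n_cells_per_image,
    )
    slide_idx = np.repeat(
        np.arange(config.n_slides), config.n_images_per_slide * config.n_cells_per_image
    )

    # marker baselines staggered so channels are distinguishable
    mu = config.base_log_mean + 0.25 * np.arange(config.n_markers)
    p_pos = config.positive_fractions
    u = rng.normal(0.0, config.slide_effect_sd, size=(config.n_slides, config.n_markers))

    data = {"slide_id": slides, "image_id": images}
    for m in range(config.n_markers):
        z = rng.random(n_cells) < p_pos[m]
        log_y = mu[m] + z * config.mixture_separation * config.noise_sd
        eps = rng.standard_normal(n_cells)
        if config.slide_effect_type == "scale":
            sigma = config.noise_sd * np.exp(u[slide_idx, m])
            log_y = log_y + sigma * eps
        else:
            log_y = log_y + config.noise_sd * eps
        if config.slide_effect_type == "multiplicative":
            log_y = log_y + u[slide_idx, m]
        y = np.exp(log_y)
        if config.slide_effect_type == "additive":
            y = np.maximum(y + u[slide_idx, m], 0.0)
        data[f"marker{m + 1}_vals"] = y
    for j in range(config.n_metadata):
        data[f"metadata{j + 1}_vals"] = rng.integers(0, 2, size=n_cells)
    return pd.DataFrame(data)


def simulate_dataset(config: SimConfig) -> MxDataset:
    """Convenience: simulate a cell table and wrap it in a validated dataset."""
    table = simulate_cells(config)
    return create_dataset(
        table,
        slide_id="slide_id",
        image_id="image_id",
        marker_cols=[f"marker{m + 1}_vals" for m in range(config.n_markers)],
        metadata_cols=[f"metadata{j + 1}_vals" for j in range(config.n_metadata)],
    )
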