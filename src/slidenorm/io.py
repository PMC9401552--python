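"""CSV ingestion, run configuration, and the end-to-end pipeline driver.

The pipeline persists every intermediate result as a plain CSV so each
stage is inspectable and re-runnable: ``normalized.csv``,
``discordance.csv``, ``umap.csv``, ``var_props.csv``, ``summary.csv``,
``summary.txt`` and the four diagnostic figures.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .core_data import MissingColumnError, MxDataset, create_dataset
from .evaluation import (
    run_otsu_discordance,
    run_reduce_umap,
    run_var_proportions,
    summarize_dataset,
)
from .normalization import normalize
from .visualization import (
    plot_density,
    plot_discordance,
    plot_proportions,
    plot_umap,
)

__all__ = ["read_cell_csv", "RunConfig", "run_pipeline"]

log = logging.getLogger("slidenorm")


def read_cell_csv(
    path,
    slide_id: str,
    image_id: str,
    marker_cols: Sequence[str],
    metadata_cols: Sequence[str] = (),
) -> MxDataset:
    """Read a long-format cell CSV and validate it into an :class:`MxDataset`.

    Comma-delimited, UTF-8, first row header. Marker columns that fail
    numeric parsing are reported with the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input CSV not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    wanted = [slide_id, image_id, *marker_cols, *metadata_cols]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise MissingColumnError(f"CSV {path} header is missing columns: {missing}")
    for col in marker_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValueError(
                f"marker column {col!r} in {path} has unparsable numeric values "
                f"at rows (0-based) {rows}{'...' if bad.sum() > 5 else ''}"
            )
    return create_dataset(df, slide_id, image_id, list(marker_cols), list(metadata_cols))


@dataclass
class RunConfig:
    """Everything needed to run the full pipeline from a CSV to artifacts."""

    input: str
    slide_id: str = "slide_id"
    image_id: str = "image_id"
    marker_cols: list[str] = field(default_factory=list)
    metadata_cols: list[str] = field(default_factory=list)
    transform: str = "None"
    method: str = "None"
    table: str = "both"
    run_discordance: bool = True
    run_umap: bool = True
    run_varprops: bool = True
    umap_markers: Optional[list[str]] = None
    downsample_pct: float = 1.0
    seed: Optional[int] = None
    output_dir: str = "slidenorm_out"
    figure_format: str = "png"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.marker_cols:
            raise ValueError("config must name at least one marker column")
        roles = [self.slide_id, self.image_id, *self.marker_cols, *self.metadata_cols]
        if len(set(roles)) != len(roles):
            raise ValueError("column roles overlap; slide/image/marker/metadata must be disjoint")
        if self.run_umap and self.seed is None:
            raise ValueError("a seed is mandatory when the UMAP analysis is enabled")
        if not (0.0 < self.downsample_pct <= 1.0):
            raise ValueError("downsample_pct must lie in (0, 1]")


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> int:
    """Create -> normalize -> analyses -> summary + figures; returns exit status.

    Any stage error is logged with the stage name and re-raised after
    partial outputs have been preserved; the CLI maps it to a nonzero exit.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("create"):
        ds = read_cell_csv(
            config.input,
            config.slide_id,
            config.image_id,
            config.marker_cols,
            config.metadata_cols,
        )

    with _stage("normalize"):
        ds = normalize(ds, transform=config.transform, method=config.method)
        ds.norm_data.to_csv(out / "normalized.csv", index=False)

    if config.run_discordance:
        with _stage("discordance"):
            ds = run_otsu_discordance(ds, table=config.table)
            ds.discordance.to_csv(out / "discordance.csv", index=False)

    if config.run_umap:
        with _stage("umap"):
            ds = run_reduce_umap(
                ds,
                table=config.table,
                marker_list=config.umap_markers or config.marker_cols,
                downsample_pct=config.downsample_pct,
                metadata_cols=config.metadata_cols,
                seed=int(config.seed),
            )
            ds.umap.to_csv(out / "umap.csv", index=False)

    if config.run_varprops:
        with _stage("var_proportions"):
            ds = run_var_proportions(ds, table=config.table)
            ds.var_props.to_csv(out / "var_props.csv", index=False)

    with _stage("summary"):
        report = summarize_dataset(ds)
        report.to_csv(out / "summary.csv")
        (out / "summary.txt").write_text(report.to_text(), encoding="utf-8")

    with _stage("figures"):
        fmt = config.figure_format
        handles = {"density": plot_density(ds, table=config.table)}
        if ds.discordance is not None:
            handles["discordance"] = plot_discordance(ds)
        if ds.umap is not None:
            handles["umap"] = plot_umap(ds, color_by="slide_id")
        if ds.var_props is not None:
            handles["proportions"] = plot_proportions(ds)
        for name, handle in handles.items():
            handle.save(out / f"{name}.{fmt}")
            handle.close()

    log.info("pipeline complete; artifacts in %s", out)
    return 0
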