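"""End-to-end pipeline orchestration with config, logging and a manifest.

Stages: simulate (optional) -> preprocess -> correlation maps and/or
classification. Every run writes a JSON manifest listing each artifact with
its SHA-256 content hash; identical config and seeds give identical hashes
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import SplitSpec, prepare_features, split_dataset, train_and_evaluate
from .corrmap import find_hotspot, per_group_maps
from .grid import WavelengthGrid, canonical_grid
from .io import (
    SpectraSet,
    join_spectra_meta,
    read_meta_csv,
    read_spectra_csv,
    write_meta_csv,
    write_spectra_csv,
)
from .plots import plot_correlation_map, plot_importance, plot_summary_spectra
from .preprocess import summary_spectra
from .synth import LeafModelParams, NiBandParams, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: Path = Path("nicospec-run")
    seed: int = 0
    log_level: str = "INFO"
    # simulate stage (skipped when spectra/meta paths are given)
    simulate: bool = True
    n_hyper: int = 100
    n_normal: int = 100
    state: str = "dehydrated"
    noise_sd: float = 0.005
    # existing inputs
    spectra_path: Path | None = None
    meta_path: Path | None = None
    # corrmap stage
    run_corrmap: bool = True
    group_by: tuple[str, ...] = ("species", "state")
    alpha_level: float = 0.05
    fdr: bool = False
    method: str = "pearson"
    write_matrices: bool = False
    # classify stage
    run_classify: bool = True
    train_fraction: float = 0.75
    n_trees: int = 100
    label_from: str = "threshold"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.spectra_path is not None:
            cfg.spectra_path = Path(cfg.spectra_path)
        if cfg.meta_path is not None:
            cfg.meta_path = Path(cfg.meta_path)
        cfg.group_by = tuple(cfg.group_by)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        d["group_by"] = list(self.group_by)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the artifact manifest.

    The manifest (also written to ``manifest.json`` in the output
    directory) maps each artifact path to its SHA-256 hash and records the
    resolved config and seeds.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    logger.info("nicospec %s: starting run, seed=%d", __version__, config.seed)
    logger.info("resolved config: %s", json.dumps(config.to_jsonable(), sort_keys=True))

    if config.simulate:
        leaf = LeafModelParams(noise_sd=config.noise_sd)
        spectra, meta = generate_dataset(
            n_hyper=config.n_hyper,
            n_normal=config.n_normal,
            state=config.state,
            leaf_params=leaf,
            seed=config.seed,
        )
        spectra_path = out / "spectra.csv"
        meta_path = out / "meta.csv"
        write_spectra_csv(spectra, spectra_path)
        write_meta_csv(meta, meta_path)
        artifacts += [spectra_path, meta_path]
    else:
        if config.spectra_path is None or not Path(config.spectra_path).exists():
            raise FileNotFoundError(
                f"simulate disabled and spectra path missing: {config.spectra_path}"
            )
        if config.meta_path is None or not Path(config.meta_path).exists():
            raise FileNotFoundError(
                f"simulate disabled and metadata path missing: {config.meta_path}"
            )
        spectra = read_spectra_csv(config.spectra_path)
        meta = read_meta_csv(config.meta_path)
    spectra, meta = join_spectra_meta(spectra, meta)

    summ = summary_spectra(spectra)
    p = out / "summary_spectra.png"
    plot_summary_spectra(summ, p)
    artifacts.append(p)

    if config.run_corrmap:
        maps = per_group_maps(
            spectra,
            meta,
            grouping=config.group_by,
            alpha_level=config.alpha_level,
            fdr=config.fdr,
            method=config.method,
        )
        hotspot_rows = []
        for key, cmap in maps.items():
            tag = "_".join(str(k) for k in key)
            if config.write_matrices:
                wl = cmap.grid.wavelengths
                # row = beta wavelength, column = alpha wavelength
                for name, arr in (("r", cmap.r), ("p", cmap.p), ("mask", cmap.mask)):
                    df = pd.DataFrame(arr.T, index=wl, columns=wl)
                    df.index.name = "beta_nm\\alpha_nm"
                    mpath = out / f"corrmap_{tag}_{name}.csv"
                    df.to_csv(mpath, float_format="%.6g", lineterminator="\n")
                    artifacts.append(mpath)
            fig_path = out / f"corrmap_{tag}.png"
            plot_correlation_map(cmap, fig_path, title=f"{key} (n={cmap.n})")
            artifacts.append(fig_path)
            if not cmap.mask.all():
                hs = find_hotspot(cmap)
                hotspot_rows.append(
                    {
                        "group": tag,
                        "n": cmap.n,
                        "alpha_nm": hs.alpha_nm,
                        "beta_nm": hs.beta_nm,
                        "r": hs.r_value,
                        "p": hs.p_value,
                    }
                )
        hs_path = out / "hotspots.csv"
        pd.DataFrame(hotspot_rows).to_csv(
            hs_path, index=False, float_format="%.10g", lineterminator="\n"
        )
        artifacts.append(hs_path)

    if config.run_classify:
        features, labels = prepare_features(spectra, meta, label_from=config.label_from)
        if len(np.unique(labels)) < 2:
            logger.warning("single-class dataset: classification stage skipped")
        else:
            split = SplitSpec(
                train_fraction=config.train_fraction, stratified=True, seed=config.seed
            )
            train, validation = split_dataset(features, labels, split)
            report = train_and_evaluate(
                train, validation, spectra.grid,
                n_trees=config.n_trees, seed=config.seed,
            )
            rep_path = out / "classifier_report.json"
            rep_path.write_text(json.dumps(report.to_jsonable(), indent=2) + "\n")
            imp_path = out / "importance.csv"
            pd.DataFrame(
                {
                    "wavelength_nm": spectra.grid.wavelengths,
                    "importance": report.importance,
                }
            ).to_csv(imp_path, index=False, float_format="%.10g", lineterminator="\n")
            fig_path = out / "importance.png"
            plot_importance(
                report.importance, spectra.grid, fig_path, region=report.dominant_region
            )
            artifacts += [rep_path, imp_path, fig_path]
            logger.info(
                "classification: accuracy=%.3f dominant region=%s nm",
                report.validation_accuracy,
                report.dominant_region,
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote %d artifact(s) to %s", len(artifacts), out)
    return manifest
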