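"""End-to-end orchestration: simulate (or read) -> preprocess -> indices ->
PCA -> regression, with a manifest that makes the run reproducible.

Outputs written to the run directory:

* ``indices.csv``            — per-sample spectral indices
* ``scores.csv``             — PC1/PC2 scores joined with metadata
* ``explained_variance.csv`` — per-component explained-variance percentages
* ``regression_report.csv``  — index-vs-cellulose fit summary
* ``manifest.json``          — resolved config, its hash, seed, versions
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

from . import io as fio
from .bands import compute_index_table
from .pca import fit_pca, loo_cross_validation, pca_pretreat, scores_vs_dpa
from .preprocess import PreprocessConfig
from .regression import correlate_indices
from .synth import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run", "load_run_config"]

log = logging.getLogger("fiberspec")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "fiberspec_run"
    simulate: bool = True
    spectra_path: str | None = None
    metadata_path: str | None = None
    cellulose_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    pca_components: int = 5
    loo_press: bool = False
    by_genotype: bool = False
    log_level: str = "INFO"
    seed: int = 42

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"] = dataclasses.asdict(self.preprocess)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["synthetic"]["band_library"] = [
            dataclasses.asdict(b) for b in self.synthetic.band_library
        ]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    pp = PreprocessConfig(**{
        k: tuple(v) if k == "norm_region" else v
        for k, v in (doc.pop("preprocess", {}) or {}).items()
    })
    synth_doc = doc.pop("synthetic", {}) or {}
    for key in ("dpa_list", "genotypes", "ramp"):
        if key in synth_doc:
            synth_doc[key] = tuple(synth_doc[key])
    seed = doc.get("seed")
    if seed is not None:
        synth_doc.setdefault("seed", seed)
    synth = SyntheticConfig(**synth_doc)
    return RunConfig(preprocess=pp, synthetic=synth, **doc)


def _setup_logging(config: RunConfig, out_dir: Path) -> None:
    log.setLevel(config.log_level.upper())
    log.handlers.clear()
    stream = logging.StreamHandler()
    stream.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(stream)
    fileh = logging.FileHandler(out_dir / "run.log", mode="w")
    fileh.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    log.addHandler(fileh)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a run report (files + summary)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)
    outputs: dict[str, str] = {}
    report: dict = {"outputs": outputs, "config_hash": config.config_hash()}

    stage = "input"
    try:
        if config.simulate:
            synth = dataclasses.replace(config.synthetic, seed=config.seed)
            log.info("simulating dataset (seed=%d, mode=%s)", synth.seed, synth.latent_mode)
            dataset, cellulose = generate_dataset(synth)
        else:
            if not (config.spectra_path and config.metadata_path):
                raise FileNotFoundError("non-simulated run needs spectra and metadata paths")
            log.info("reading spectra from %s", config.spectra_path)
            dataset = fio.read_spectra(config.spectra_path, config.metadata_path)
            if not config.cellulose_path:
                raise FileNotFoundError("non-simulated run needs a cellulose table")
            cellulose = fio.read_cellulose(config.cellulose_path)
        log.info("dataset: %d samples on a %d-point grid", len(dataset), dataset.grid.size)

        stage = "indices"
        indices = compute_index_table(dataset, config.preprocess)
        path = out_dir / "indices.csv"
        fio.write_index_table(indices, path)
        outputs["indices"] = str(path)

        stage = "pca"
        matrix, _ = pca_pretreat(dataset, config.preprocess)
        dpa = np.array([s.dpa for s in dataset])
        n_comp = min(config.pca_components, len(dataset) - 1, matrix.shape[1])
        model = fit_pca(matrix, n_comp, dpa=dpa)
        scores = scores_vs_dpa(model, dataset)
        path = out_dir / "scores.csv"
        scores.to_csv(path, index=False, float_format="%.12g")
        outputs["scores"] = str(path)

        ev = pd.DataFrame(
            {
                "component": np.arange(1, n_comp + 1),
                "explained_variance_pct": model.explained_variance_pct,
                "cumulative_pct": np.cumsum(model.explained_variance_pct),
            }
        )
        if config.loo_press:
            ev["loo_press"] = loo_cross_validation(matrix, n_comp)
        path = out_dir / "explained_variance.csv"
        ev.to_csv(path, index=False, float_format="%.12g")
        outputs["explained_variance"] = str(path)
        log.info(
            "PC1 %.1f%%, PC1+PC2 %.1f%% of variance",
            ev["explained_variance_pct"].iloc[0],
            ev["cumulative_pct"].iloc[min(1, n_comp - 1)],
        )

        stage = "regression"
        reg = correlate_indices(indices, cellulose, scores, by_genotype=config.by_genotype)
        path = out_dir / "regression_report.csv"
        reg.to_csv(path, index=False, float_format="%.12g")
        outputs["regression_report"] = str(path)

        report["summary"] = {
            "n_samples": len(dataset),
            "pc1_pct": float(ev["explained_variance_pct"].iloc[0]),
            "pc12_pct": float(ev["cumulative_pct"].iloc[min(1, n_comp - 1)]),
            "linear_r2": {
                row["response"]: float(row["linear_r2"])
                for _, row in reg[reg["genotype"] == "all"].iterrows()
            },
        }
        report["status"] = "ok"
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _write_manifest(config, report, out_dir, partial=True)
        raise

    _write_manifest(config, report, out_dir, partial=False)
    return report


def _write_manifest(config: RunConfig, report: dict, out_dir: Path, partial: bool) -> None:
    import fiberspec

    manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "fiberspec": fiberspec.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "partial": partial,
        "report": {k: v for k, v in report.items() if k != "outputs"},
        "outputs": report.get("outputs", {}),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
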