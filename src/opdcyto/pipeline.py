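"""End-to-end orchestration: simulate (or ingest) -> reconstruct ->
features -> classify -> cohort comparison, with a single flat config and a
run manifest.

The default run is feature-level (fast): per-cell features are drawn from
the calibrated class distributions. With ``render=True`` every cell is
rendered as an OPD phantom, converted to an off-axis interferogram,
reconstructed and measured — exercising the full optical chain.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from opdcyto import io as ocio
from opdcyto.classify import cdf_intersection_threshold, fit_logistic_cv
from opdcyto.cohort import compare_groups, make_cohort_sample
from opdcyto.errors import NoCellFoundError
from opdcyto.morphometry import compute_features, segment_cell
from opdcyto.phantom import (
    CohortParams,
    H_FEATURE_MEANS,
    L_FEATURE_MEANS,
    RELATIVE_SD,
    make_cell_phantom,
    sample_class_features,
    sample_cohort_features,
    spec_from_features,
    synthesize_interferogram,
)
from opdcyto.reconstruction import (
    DEFAULT_CARRIER,
    OBJECT_PIXEL_PITCH_UM,
    WAVELENGTH_NM,
    OpticsConfig,
    reconstruct_opd,
)

logger = logging.getLogger("opdcyto")

CLASSIFIER_CHOICES = ("dry_mass_threshold", "opd_threshold", "logistic")


@dataclass
class PipelineConfig:
    """Flat configuration of a full synthetic run.

    Every tunable of the pipeline appears here with a default; the YAML
    serialization round-trips losslessly.
    """

    seed: int = 0
    out_dir: str = "opdcyto_run"
    input_dir: str | None = None  # ingest feature CSVs instead of simulating
    # training ("sorted cells") stage
    n_train_h: int = 77
    n_train_l: int = 94
    # cohort stage
    n_cells_bbd: int = 575
    n_cells_mds: int = 481
    n_samples_bbd: int = 8
    n_samples_mds: int = 5
    h_fraction_bbd: float = 0.20
    h_fraction_mds: float = 0.04
    # optics / rendering
    render: bool = False
    emit_interferograms: bool = False
    noise_sd: float = 0.0
    wavelength_nm: float = WAVELENGTH_NM
    object_pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM
    carrier_fy: float = DEFAULT_CARRIER[0]
    carrier_fx: float = DEFAULT_CARRIER[1]
    fourier_window_radius: float | None = None
    flatten_order: int = 2
    # segmentation
    opd_threshold_nm: float = 40.0
    dilation_radius_px: int = 2
    perimeter_estimator: str = "weighted"
    # classification
    classifier: str = "dry_mass_threshold"
    cv_folds: int = 5
    # gating
    gate_lo_pct: float = 5.0
    gate_hi_pct: float = 95.0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_CHOICES:
            raise ValueError(
                f"classifier must be one of {CLASSIFIER_CHOICES}, "
                f"got {self.classifier!r}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def optics(self) -> OpticsConfig:
        return OpticsConfig(
            wavelength_nm=self.wavelength_nm,
            object_pixel_pitch_um=self.object_pixel_pitch_um,
            carrier_frequency=(self.carrier_fy, self.carrier_fx),
            fourier_window_radius=self.fourier_window_radius,
        )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    counts: dict
    started: str
    finished: str
    outputs: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def render_features(
    df: pd.DataFrame, config: PipelineConfig, seed: int,
    interferogram_dir: Path | None = None,
) -> pd.DataFrame:
    """Run drawn cells through the full optical chain.

    Each feature row becomes a phantom (radius from drawn area, mass from
    drawn dry mass); an interferogram is rendered on the phantom's own
    raster, reconstructed, segmented and measured. Cells whose
    reconstruction yields no segmentable object are logged and skipped.
    """
    optics = config.optics()
    seeds = _child_seeds(seed, len(df))
    rows = []
    for i, (_, row) in enumerate(df.iterrows()):
        truth = make_cell_phantom(
            spec_from_features(row, seeds[i], config.object_pixel_pitch_um))
        ig = synthesize_interferogram(
            truth, optics, noise_sd=config.noise_sd, frame_shape=None,
            rng_seed=seeds[i])
        if interferogram_dir is not None:
            ocio.write_interferogram(ig, interferogram_dir / f"{row.cell_id}.png")
        opd = reconstruct_opd(ig, optics, flatten_order=config.flatten_order)
        try:
            mask = segment_cell(opd, config.opd_threshold_nm,
                                config.dilation_radius_px)
        except NoCellFoundError:
            logger.warning("segmentation failed for cell %s; skipped", row.cell_id)
            continue
        feats = compute_features(
            opd, mask, cell_id=row.cell_id, sample_id=row.sample_id,
            label=row.label, perimeter_estimator=config.perimeter_estimator)
        rows.append(feats.to_dict())
    return pd.DataFrame(rows)


def _training_table(config: PipelineConfig, seed: int,
                    render_dir: Path | None) -> pd.DataFrame:
    s1, s2 = _child_seeds(seed, 2)
    rng_h = np.random.default_rng(s1)
    rng_l = np.random.default_rng(s2)
    h_sds = {k: RELATIVE_SD * v for k, v in H_FEATURE_MEANS.items()}
    l_sds = {k: RELATIVE_SD * v for k, v in L_FEATURE_MEANS.items()}
    df = pd.concat([
        sample_class_features("H", config.n_train_h, H_FEATURE_MEANS, h_sds,
                              rng_h, sample_id="sorted"),
        sample_class_features("L", config.n_train_l, L_FEATURE_MEANS, l_sds,
                              rng_l, sample_id="sorted"),
    ], ignore_index=True)
    if config.render:
        df = render_features(df, config, seed, render_dir)
    return df


def _fit_model(train: pd.DataFrame, config: PipelineConfig, seed: int):
    h = train.loc[train.label == "H"]
    l = train.loc[train.label == "L"]
    if config.classifier == "dry_mass_threshold":
        return cdf_intersection_threshold(h.dry_mass_pg, l.dry_mass_pg,
                                          feature_name="dry_mass")
    if config.classifier == "opd_threshold":
        return cdf_intersection_threshold(h.avg_opd_nm, l.avg_opd_nm,
                                          feature_name="avg_opd")
    return fit_logistic_cv(train, k=config.cv_folds, seed=seed)


def _cohort_tables(config: PipelineConfig, seed: int,
                   render_dir: Path | None) -> dict[str, list[pd.DataFrame]]:
    """Per-group lists of per-donor feature tables."""
    plans = {
        "BBD": (config.n_cells_bbd, config.n_samples_bbd, config.h_fraction_bbd),
        "MDS": (config.n_cells_mds, config.n_samples_mds, config.h_fraction_mds),
    }
    seeds = _child_seeds(seed, sum(p[1] for p in plans.values()))
    out: dict[str, list[pd.DataFrame]] = {}
    k = 0
    for group, (n_cells, n_samples, h_frac) in plans.items():
        sizes = [n_cells // n_samples] * n_samples
        sizes[0] += n_cells - sum(sizes)
        tables = []
        for j, size in enumerate(sizes):
            params = CohortParams(group_label=group, n_cells=size,
                                  h_fraction=h_frac, rng_seed=seeds[k])
            df = sample_cohort_features(params, sample_id=f"{group}-{j + 1:02d}")
            if config.render:
                df = render_features(df, config, seeds[k], render_dir)
            tables.append(df)
            k += 1
        out[group] = tables
    return out


def run_end_to_end(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Stages: simulate (or ingest) the sorted training cells and the two
    cohorts; optionally render/reconstruct; fit the configured classifier;
    perimeter-gate the cohorts against the training (sorted-cell)
    perimeter distribution; compare pooled group H fractions. Fully
    reproducible from the config and its seed.
    """
    started = datetime.now(timezone.utc).isoformat()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ig_dir = None
    if config.emit_interferograms:
        ig_dir = out / "interferograms"
        ig_dir.mkdir(exist_ok=True)

    seed_train, seed_cohort, seed_fit = _child_seeds(config.seed, 3)

    if config.input_dir is not None:
        src = Path(config.input_dir)
        if not src.is_dir():
            raise FileNotFoundError(f"input directory does not exist: {src}")
        train = ocio.read_features_csv(src / "train_features.csv")
        group_tables = {}
        for group in ("BBD", "MDS"):
            df = ocio.read_features_csv(src / f"{group.lower()}_features.csv")
            group_tables[group] = [g for _, g in df.groupby("sample_id", sort=True)]
    else:
        train = _training_table(config, seed_train, ig_dir)
        group_tables = _cohort_tables(config, seed_cohort, ig_dir)

    model = _fit_model(train, config, seed_fit)

    reference_perimeters = train["perimeter_um"].to_numpy()
    samples = []
    counts = {"train_h": int((train.label == "H").sum()),
              "train_l": int((train.label == "L").sum())}
    for group, tables in group_tables.items():
        before = after = 0
        for df in tables:
            cs = make_cohort_sample(str(df.sample_id.iloc[0]), group, df,
                                    reference_perimeters,
                                    config.gate_lo_pct, config.gate_hi_pct)
            samples.append(cs)
            before += cs.n_before_gate
            after += cs.n_after_gate
        counts[f"{group.lower()}_generated"] = before
        counts[f"{group.lower()}_gated"] = after

    comparison = compare_groups(samples, model)

    ocio.write_features_csv(train, out / "train_features.csv")
    for group, tables in group_tables.items():
        ocio.write_features_csv(pd.concat(tables, ignore_index=True),
                                out / f"{group.lower()}_features.csv")
    model.to_json(out / "model.json")
    results = {
        "classifier": config.classifier,
        "model": json.loads((out / "model.json").read_text()),
        "group_counts": {g: list(c) for g, c in comparison.group_counts.items()},
        "group_h_fractions": comparison.group_fractions,
        "test_name": comparison.test_name,
        "statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "alpha": comparison.alpha,
        "significant": comparison.significant,
        "per_sample": comparison.per_sample.to_dict(orient="records"),
    }
    (out / "results.json").write_text(json.dumps(results, indent=2) + "\n")
    comparison.per_sample.to_csv(out / "per_sample.csv", index=False)
    config.to_yaml(out / "config.yaml")

    from opdcyto import __version__

    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        counts=counts,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        outputs={
            "train_features": str(out / "train_features.csv"),
            "bbd_features": str(out / "bbd_features.csv"),
            "mds_features": str(out / "mds_features.csv"),
            "model": str(out / "model.json"),
            "results": str(out / "results.json"),
            "per_sample": str(out / "per_sample.csv"),
        },
    )
    manifest.to_json(out / "manifest.json")
    return manifest
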