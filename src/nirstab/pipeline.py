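"""End-to-end analysis: preprocess, fit reference, score, compare cups.

:func:`analyze_study` is the library entry point — it takes one raw
SpectrumSet containing products, standards and (optionally) empty pads,
preprocesses everything consistently against the reference brand's
standard-set MSC reference, fits the reference model, and returns the
stability timeline, the inter-brand distances, the cup-equivalence
comparison and PCA scores.

:func:`run_pipeline` wraps it for the CLI: simulate (or load) the study,
run the analysis, and write a report bundle (stability CSVs, equivalence
JSON, PCA scores CSV) cross-referenced by an append-only run manifest
holding the config snapshot, seed, per-stage parameters and SHA-256
digests of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from . import __version__
from .equivalence import EquivalenceResult, compare_groups, pair_up, paired_distance
from .errors import ValidationError
from .io import write_csv_spectra
from .preprocess import PreprocessConfig, preprocess_pipeline, smoothed_reference
from .similarity import (
    ReferenceModel,
    StabilityResult,
    fit_reference,
    mahalanobis_D,
    pca_scores,
    stability_timeline,
)
from .spectra import Role, SpectrumSet
from .simulate import StudyConfig, simulate_study, study_config_to_dict

__all__ = ["AnalysisReport", "analyze_study", "run_pipeline", "RunManifest"]


@dataclass
class AnalysisReport:
    """Everything the analysis computes, in memory."""

    model: ReferenceModel
    stability: StabilityResult  # reference-brand products vs their standard
    inter_brand: pd.DataFrame  # other brands' samples vs the same reference
    equivalence: EquivalenceResult
    pca: pd.DataFrame
    summary: dict


def analyze_study(
    study: SpectrumSet,
    reference_brand: str = "TT",
    preprocess_config: PreprocessConfig | None = None,
    method: str = "pca_subspace",
    variance_retained: float = 0.99,
    n_bins: int = 30,
    n_pca_components: int = 2,
    average_batches: bool = True,
) -> AnalysisReport:
    """Run the full similarity analysis on one raw study set.

    All spectra — standards and products of every brand — are preprocessed
    with the MSC reference fixed to the reference brand's smoothed
    standard-set mean, so each spectrum's score is independent of which
    other spectra happen to share its file.
    """
    cfg = preprocess_config or PreprocessConfig()
    standards_raw = study.select(role=Role.STANDARD, brand=reference_brand)
    msc_ref = smoothed_reference(standards_raw, cfg)
    standards_pp = preprocess_pipeline(standards_raw, cfg, explicit_reference=msc_ref)
    model = fit_reference(
        standards_pp,
        method=method,
        variance_retained=variance_retained,
        msc_reference=msc_ref,
        preprocess_config=cfg,
    )

    products_raw = study.select(role=Role.PRODUCT)
    products_pp = preprocess_pipeline(products_raw, cfg, explicit_reference=msc_ref)

    intra = products_pp.select(brand=reference_brand)
    stability = stability_timeline(intra, model, average_batches=average_batches)

    other_brands = sorted(
        {s.meta.brand for s in products_pp} - {reference_brand}
    )
    inter_rows = []
    for s in products_pp:
        if s.meta.brand in other_brands:
            inter_rows.append(
                {
                    "sample_id": s.meta.sample_id,
                    "brand": s.meta.brand,
                    "batch_id": s.meta.batch_id,
                    "date_index": s.meta.date_index,
                    "D": mahalanobis_D(s, model),
                }
            )
    inter_brand = (
        pd.DataFrame(inter_rows, columns=["sample_id", "brand", "batch_id", "date_index", "D"])
        .sort_values(["date_index", "sample_id"], kind="stable")
        .reset_index(drop=True)
    )

    # paired distances within every brand, under the one reference metric
    pairs, _ = pair_up(products_pp)
    paired = [(p.pair_id, paired_distance(p, model)) for p in pairs]
    sample = list(
        stability.per_sample[["sample_id", "D"]].itertuples(index=False, name=None)
    )
    equivalence = compare_groups(paired, sample, n_bins=n_bins)

    pca = pca_scores(products_pp, n_components=n_pca_components)
    labels = pca["brand"].to_numpy()
    scores = pca[[f"PC{j + 1}" for j in range(n_pca_components)]].to_numpy()
    silhouette = (
        float(silhouette_score(scores, labels)) if len(set(labels)) > 1 else float("nan")
    )

    summary = dict(equivalence.summary)
    summary.update(
        {
            "reference_brand": reference_brand,
            "method": model.method,
            "k": model.k,
            "n_standards": model.n_ref,
            "median_inter_brand": (
                float(inter_brand["D"].median()) if len(inter_brand) else float("nan")
            ),
            "brand_silhouette": silhouette,
        }
    )
    return AnalysisReport(
        model=model,
        stability=stability,
        inter_brand=inter_brand,
        equivalence=equivalence,
        pca=pca,
        summary=summary,
    )


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    seed: int
    config: dict
    stages: dict
    package_version: str = __version__
    digests: dict | None = None
    started: str = ""
    finished: str = ""

    def to_json_dict(self) -> dict:
        return {
            "package_version": self.package_version,
            "seed": self.seed,
            "config": self.config,
            "stages": self.stages,
            "digests": self.digests or {},
            "started": self.started,
            "finished": self.finished,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    study_config: StudyConfig,
    out_dir: str | Path,
    reference_brand: str = "TT",
    preprocess_config: PreprocessConfig | None = None,
    method: str = "pca_subspace",
    variance_retained: float = 0.99,
    n_bins: int = 30,
    write_simulated: bool = False,
) -> AnalysisReport:
    """simulate -> preprocess -> fit-reference -> score -> equivalence.

    Deterministic given the study config's seed.  Writes the report bundle
    under ``out_dir`` and returns the in-memory report.  Any stage failure
    aborts with the stage name; the manifest written so far is included in
    the error message's context.
    """
    study_config.validate()  # fail before any stage runs
    if reference_brand not in study_config.brands:
        raise ValidationError(
            f"reference brand {reference_brand!r} not among study brands "
            f"{sorted(study_config.brands)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = preprocess_config or PreprocessConfig()
    manifest = RunManifest(
        seed=study_config.seed,
        config=study_config_to_dict(study_config),
        stages={
            "preprocess": cfg.to_dict(),
            "fit_reference": {
                "method": method,
                "variance_retained": variance_retained,
                "reference_brand": reference_brand,
            },
            "equivalence": {"n_bins": n_bins},
        },
        started=datetime.now(timezone.utc).isoformat(),
    )

    study = simulate_study(study_config)
    written: dict[str, Path] = {}
    if write_simulated:
        written["simulated_csv"] = write_csv_spectra(study, out_dir / "simulated.csv")

    report = analyze_study(
        study,
        reference_brand=reference_brand,
        preprocess_config=cfg,
        method=method,
        variance_retained=variance_retained,
        n_bins=n_bins,
    )

    p = out_dir / "stability_samples.csv"
    report.stability.per_sample.to_csv(p, index=False)
    written["stability_samples_csv"] = p
    if report.stability.per_batch is not None:
        p = out_dir / "stability_batches.csv"
        report.stability.per_batch.to_csv(p, index=False)
        written["stability_batches_csv"] = p
    p = out_dir / "interbrand_samples.csv"
    report.inter_brand.to_csv(p, index=False)
    written["interbrand_samples_csv"] = p
    p = out_dir / "pca_scores.csv"
    report.pca.to_csv(p, index=False)
    written["pca_scores_csv"] = p
    p = out_dir / "equivalence.json"
    payload = report.equivalence.to_json_dict()
    payload["summary"] = report.summary
    p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written["equivalence_json"] = p
    p = out_dir / "model.json"
    p.write_text(json.dumps(report.model.to_json_dict()) + "\n")
    written["model_json"] = p

    manifest.digests = {name: _sha256(path) for name, path in written.items()}
    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report
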