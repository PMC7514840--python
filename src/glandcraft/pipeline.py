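"""End-to-end orchestration: simulate -> maps -> features -> selection ->
nested CV -> reports, driven by a serialisable run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .crossval import nested_cv
from .features.extract import extract_table
from .features.schema import write_schema_json
from .io import write_cohort, write_feature_table, write_report, write_selection
from .phantom import PhantomSpec, generate_cohort
from .selection import FeatureTable, select_features
from .utils import derive_seed

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # phantom generation (ignored when input_dir is set)
    input_dir: str | None = None
    phantom: dict = field(default_factory=dict)
    use_truth_maps: bool = True
    # selection
    alpha: float = 1e-6
    r_thresh: float = 0.95
    # modelling
    classifier: str = "svm"
    k_outer: int = 5
    k_inner: int = 10
    svm_budget: int = 30
    svm_method: str = "bayes"
    export_cohort: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full hand-driven pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None and not Path(config.input_dir).exists():
        raise FileNotFoundError(f"input directory {config.input_dir} does not exist")

    spec = PhantomSpec(seed=derive_seed(config.seed, "phantom"), **config.phantom)
    cohort = generate_cohort(spec)
    if config.export_cohort:
        write_cohort(cohort, out / "cohort")

    df = extract_table(cohort, seed=config.seed,
                       use_truth_maps=config.use_truth_maps)
    write_feature_table(df, out / "features.csv")
    write_schema_json(out / "feature_schema.json")

    table = FeatureTable.from_dataframe(df)
    sel = select_features(table, alpha=config.alpha, r_thresh=config.r_thresh)
    write_selection(sel, out / "selection.json")
    (out / "selected_features.txt").write_text("\n".join(sel.selected_names) + "\n")

    report = nested_cv(table, classifier=config.classifier,
                       k_outer=config.k_outer, k_inner=config.k_inner,
                       seed=config.seed, alpha=config.alpha,
                       r_thresh=config.r_thresh, svm_budget=config.svm_budget,
                       svm_method=config.svm_method)
    write_report(report, out / "evaluation.json")

    manifest = {
        "glandcraft_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_candidates": int(len(df)),
        "n_patients": int(df["patient_id"].nunique()),
        "n_selected_features": len(sel.selected_names),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.to_yaml(out / "config.yaml")
    return out
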