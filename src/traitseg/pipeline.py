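"""End-to-end orchestration: validate -> listwise-delete incomplete sites ->
allocate traits -> diversity -> response curves -> tipping points.

Each stage reads and writes plain CSV (UTF-8, comma, header, ``site_id`` as
the join key) so stages can also be run in isolation; ``run_pipeline`` wires
them together, logs per-stage record counts, and writes a manifest with a
config hash and a checksum per output so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allocation import (
    TraitAbundanceMatrix,
    TraitAffinityTable,
    build_trait_abundance_matrix,
    filter_sparse_traits,
    validate_taxa_counts,
)
from .diversity import METRICS, diversity_profile
from .errors import ValidationError
from .models import backward_select, response_curve
from .segmented import select_tipping_point
from .synthetic import ENV_VARS, SyntheticScenario, simulate_dataset

log = logging.getLogger("traitseg")

__all__ = ["RunConfig", "filter_complete_cases", "run_pipeline", "validate_environment"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips losslessly to YAML."""

    taxa_csv: str | None = None
    affinity_csv: str | None = None
    env_csv: str | None = None
    scenario_yaml: str | None = None   # alternative to the three CSVs
    out_dir: str = "traitseg_out"
    alpha: float = 0.05
    max_zero_fraction: float = 0.9
    exclude_traits: list[list[str]] = field(default_factory=list)  # [feature, trait] pairs
    n_candidates: int = 10             # K for the existence tests
    n_starts: int = 9                  # segmented starting-value grid size
    predictors: list[str] = field(default_factory=lambda: list(ENV_VARS))
    responses: list[str] = field(default_factory=list)  # empty = all retained traits
    seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        bad = set(self.predictors) - set(ENV_VARS)
        if bad:
            raise ValidationError(f"unknown predictors {sorted(bad)}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_environment(env: pd.DataFrame) -> pd.DataFrame:
    missing = set(ENV_VARS) - set(env.columns)
    if missing:
        raise ValidationError(f"environmental table lacks columns: {sorted(missing)}")
    neg = [(v, float(env[v].min())) for v in ENV_VARS if (env[v].dropna() < 0).any()]
    if neg:
        raise ValidationError(f"environmental variables must be non-negative: {neg}")
    return env


def filter_complete_cases(env: pd.DataFrame, taxa: pd.DataFrame):
    """Listwise deletion: drop sites missing any predictor from every table.

    Returns (env, taxa, report).  The report lists every removed or annotated
    site with its reason; sites present in the environmental table but absent
    from the taxa table are retained (they represent zero-count communities)
    and noted.
    """
    validate_environment(env)
    records = []
    incomplete = env[list(ENV_VARS)].isna().any(axis=1)
    for site in env.index[incomplete]:
        gone = [v for v in ENV_VARS if pd.isna(env.loc[site, v])]
        records.append({"site_id": site, "action": "removed", "reason": f"missing {', '.join(gone)}"})
    kept = env.loc[~incomplete]
    if kept.empty:
        raise ValidationError("no sites remain after complete-case filtering")
    taxa_f = taxa[taxa["site_id"].isin(kept.index)].reset_index(drop=True)
    for site in kept.index.difference(pd.Index(taxa["site_id"].unique())):
        records.append({"site_id": site, "action": "retained", "reason": "no taxa records; zero-count community"})
    report = pd.DataFrame(records, columns=["site_id", "action", "reason"])
    return kept, taxa_f, report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.scenario_yaml:
        scenario = SyntheticScenario.from_dict(
            yaml.safe_load(Path(config.scenario_yaml).read_text()))
        return simulate_dataset(scenario, seed=config.seed)
    if not (config.taxa_csv and config.affinity_csv and config.env_csv):
        raise ValidationError("config needs either scenario_yaml or all three input CSVs")
    for p in (config.taxa_csv, config.affinity_csv, config.env_csv):
        if not Path(p).exists():
            raise ValidationError(f"input path does not exist: {p}")
    taxa = validate_taxa_counts(pd.read_csv(config.taxa_csv))
    affinity = TraitAffinityTable.from_csv(config.affinity_csv)
    env = pd.read_csv(config.env_csv, index_col="site_id")
    return taxa, affinity, env


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.content_hash(), "seed": config.seed, "outputs": {}}

    def write(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        frame.to_csv(path, **kw)
        manifest["outputs"][name] = _sha256(path)
        log.info("stage output %s: %d rows", name, len(frame))

    taxa, affinity, env = _load_inputs(config)

    env_f, taxa_f, removal = filter_complete_cases(env, taxa)
    write("site_filter_report.csv", removal, index=False)
    log.info("complete-case filter: %d -> %d sites", len(env), len(env_f))

    matrix = build_trait_abundance_matrix(taxa_f, affinity)
    # env-only sites become explicit zero-count rows
    matrix.data = matrix.data.reindex(env_f.index, fill_value=0)
    matrix = filter_sparse_traits(matrix, config.max_zero_fraction,
                                  exclude=[tuple(p) for p in config.exclude_traits] or None)
    flat = matrix.data.copy()
    flat.columns = [f"{f}::{t}" for f, t in matrix.data.columns]
    write("trait_abundance.csv", flat)
    write("trait_exclusion_report.csv", matrix.exclusion_report(), index=False)

    # diversity uses the full trait set; models use the retained set
    diversity = diversity_profile(matrix.data)
    write("diversity.csv", diversity)

    retained = matrix.retained()
    if config.responses:
        keep = [c for c in retained.columns if c[1] in config.responses]
        retained = retained[keep]

    fit_rows, curve_rows, tip_rows = [], [], []
    jobs = [(f"{f}::{t}", retained[(f, t)].to_numpy(), "negative-binomial") for f, t in retained.columns]
    jobs += [(m, diversity[m].to_numpy(dtype=float), "gaussian") for m in METRICS]
    for predictor in config.predictors:
        x = env_f[predictor].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 100)
        for name, y, family in jobs:
            if family == "negative-binomial" and y.sum() == 0:
                continue
            fit = backward_select(y, x, family, config.alpha, response=name, predictor=predictor)
            fit_rows.append({
                "response": name, "predictor": predictor, "family": fit.family,
                "form": fit.form, "b0": fit.coefficients[0],
                "b1": fit.coefficients[1] if fit.form != "intercept" else np.nan,
                "b2": fit.coefficients[2] if fit.form == "quadratic" else np.nan,
                "k": fit.k, "center": fit.center, "loglik": fit.loglik,
                "p_quadratic": fit.trace[0]["p_value"],
                "p_linear": fit.trace[1]["p_value"] if len(fit.trace) > 1 else np.nan,
                "converged": fit.converged,
            })
            mean, _ = response_curve(fit, grid)
            curve_rows += [{"response": name, "predictor": predictor, "x": g, "mean": m}
                           for g, m in zip(grid, mean)]
            tip = select_tipping_point(y, x, family, K=config.n_candidates,
                                       alpha=config.alpha, response=name, predictor=predictor)
            tip_rows.append({
                "response": name, "predictor": predictor, "family": tip.family,
                "psi": tip.psi, "psi_se": tip.psi_se, "alpha_left": tip.alpha,
                "beta1": tip.beta1, "beta2": tip.beta2, "test": tip.test_name,
                "statistic": tip.statistic, "p_value": tip.p_value,
                "significant": tip.significant, "converged": tip.converged,
                "warnings": "; ".join(tip.warnings),
            })
            if config.make_plots and tip.significant and tip.converged:
                from .plotting import plot_segmented
                plot_segmented(tip, y, x, out / f"tipping_{name.replace('::', '_')}_{predictor}.png")

    write("response_fits.csv", pd.DataFrame(fit_rows), index=False)
    write("response_curves.csv", pd.DataFrame(curve_rows), index=False)
    write("tipping_points.csv", pd.DataFrame(tip_rows), index=False)

    manifest["n_sites_input"] = int(len(env))
    manifest["n_sites_analysed"] = int(len(env_f))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
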