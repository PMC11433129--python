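"""End-to-end orchestration: one config in, a structured report bundle out.

All randomness flows from one root seed, expanded per stage with
``numpy.random.SeedSequence`` so stages are independently reproducible.
Report files carry no timestamps; two runs from the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .codebook import VariableCodebook
from .counterfactual import DecompositionResult, decompose
from .disparity import crosstab, crosstab_with_tests, flow_edges, flow_table, rate_by
from .errors import ConfigurationError
from .interpret import category_importance, explain, importance, subgroup_summary
from .model import Metrics, TuneResult, desk_search_space, evaluate, fit, tune
from .preprocess import (
    DEFAULT_EXCLUSIONS,
    DEFAULT_OPIOID_CODES,
    SplitSpec,
    prepare,
)
from .synthetic import (
    INDEPENDENT,
    UNHOUSED,
    GeneratorConfig,
    default_config,
    generate_admissions,
)
from .teds_io import read_admissions

log = logging.getLogger("moudflow")


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input source is set."""

    synthetic: GeneratorConfig | None = None
    input_csv: str | None = None
    input_codebook: str | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    tuning_budget: int = 20
    seed: int = 0
    out_dir: str = "report"
    reference_group: str = INDEPENDENT
    target_group: str = UNHOUSED
    subgroup_variable: str = "LIVARAG"
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    opioid_codes: frozenset = DEFAULT_OPIOID_CODES
    category_map: dict[str, str] | None = None

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_csv is None):
            raise ConfigurationError("set exactly one input source (synthetic or file)")
        if self.input_csv is not None and self.input_codebook is None:
            raise ConfigurationError("a file source needs a codebook path")
        if self.tuning_budget < 1:
            raise ConfigurationError("tuning budget must be >= 1")
        self.split.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration; the synthetic block overrides defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        if "synthetic" in raw:
            syn = raw["synthetic"] or {}
            cfg = default_config(
                n_admissions=int(syn.get("n_admissions", 200_000)),
                seed=int(syn.get("seed", 20190)),
            )
            kw["synthetic"] = cfg
        for key in ("input_csv", "input_codebook", "tuning_budget", "seed",
                    "out_dir", "reference_group", "target_group",
                    "subgroup_variable"):
            if key in raw:
                kw[key] = raw[key]
        if "split" in raw:
            kw["split"] = SplitSpec(**raw["split"])
        if "exclusions" in raw:
            kw["exclusions"] = tuple(raw["exclusions"])
        if "opioid_codes" in raw:
            kw["opioid_codes"] = frozenset(raw["opioid_codes"])
        return cls(**kw)

    def digest(self) -> str:
        """Stable hash of the analysis configuration (output location excluded)."""
        def default(o):
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items() if k != "out_dir"}
            if hasattr(o, "_asdict"):
                return o._asdict()
            return str(o)

        payload = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of one run plus the paths written."""

    out_dir: Path
    metrics: Metrics
    tune_result: TuneResult
    importance: "object"
    category_importance: "object"
    subgroup: "object"
    rates_by_group: "object"
    crosstab_frame: "object"
    decomposition: DecompositionResult
    manifest: dict
    paths: dict[str, Path]


def _child_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Stages: acquire -> preprocess funnel -> tune/fit/evaluate ->
    explain/importance/subgroups -> descriptive tables/flows -> counterfactual
    decomposition -> manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    funnel: dict[str, int] = {}

    # --- acquire --------------------------------------------------------
    if config.synthetic is not None:
        table = generate_admissions(config.synthetic)
    else:
        cb = VariableCodebook.from_yaml(config.input_codebook)
        table = read_admissions(config.input_csv, cb)
    funnel["input_rows"] = table.n_rows
    log.info("acquired %d admissions", table.n_rows)

    # --- preprocess -----------------------------------------------------
    split_spec = SplitSpec(
        config.split.train_fraction,
        config.split.validation_fraction,
        config.split.test_fraction,
        seed=seeds[1],
    )
    cohort, parts, matrices, labels, dropped = prepare(
        table,
        split_spec,
        balance_seed=seeds[0],
        opioid_codes=config.opioid_codes,
        exclusions=config.exclusions,
    )
    funnel["opioid_cohort_rows"] = cohort.n_rows
    funnel["unknown_outcome_dropped_fraction"] = dropped
    funnel["balanced_rows"] = sum(p.n_rows for p in parts)
    funnel["train_rows"], funnel["validation_rows"], funnel["test_rows"] = (
        p.n_rows for p in parts
    )
    log.info("cohort %d rows; balanced %d; dropped-unknown-outcome %.4f",
             cohort.n_rows, funnel["balanced_rows"], dropped)
    (train_t, val_t, test_t) = parts
    (X_tr, X_va, X_te) = matrices
    (y_tr, y_va, y_te) = labels

    # --- model ----------------------------------------------------------
    tuned = tune(X_tr, y_tr, X_va, y_va, budget=config.tuning_budget,
                 seed=seeds[2], space=desk_search_space())
    model = fit(X_tr, y_tr, tuned.best_params, seed=seeds[3])
    metrics = evaluate(model, X_te, y_te)
    log.info("test AUC %.4f, accuracy@0.5 %.4f", metrics.auc, metrics.accuracy_at_half)

    # --- interpretation -------------------------------------------------
    shap = explain(model, X_te)
    imp = importance(shap, config.category_map)
    cat_imp = category_importance(imp)
    subgroups = subgroup_summary(shap, test_t, config.subgroup_variable)

    # --- descriptive disparity (on the pre-balancing cohort) ------------
    rates_group = rate_by(cohort, config.subgroup_variable)
    ct = crosstab(cohort)
    ct_tests = crosstab_with_tests(ct, config.reference_group)
    flows = {
        g: flow_table(cohort, g)
        for g in (config.reference_group, config.target_group)
    }

    # --- counterfactual -------------------------------------------------
    deco = decompose(ct, config.reference_group, config.target_group)

    # --- write ----------------------------------------------------------
    paths: dict[str, Path] = {}

    def save_csv(name: str, df) -> None:
        paths[name] = out / f"{name}.csv"
        _write_csv(df, paths[name])

    save_csv("importance", imp)
    save_csv("category_importance", cat_imp)
    save_csv("subgroup_shap", subgroups)
    save_csv("rates_by_group", rates_group)
    save_csv("crosstab", ct.to_frame())
    save_csv("crosstab_tests", ct_tests)
    save_csv("tuning_trials", tuned.trials)
    for g, fl in flows.items():
        tag = g.lower().replace(" ", "_")
        save_csv(f"flows_{tag}", fl)
        save_csv(f"flow_edges_{tag}", flow_edges(fl, g))
    paths["metrics"] = out / "metrics.json"
    metrics.to_json(paths["metrics"])
    paths["decomposition"] = out / "decomposition.json"
    deco.to_json(paths["decomposition"])
    paths["model"] = out / "model.json"
    model.save(paths["model"])

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "root_seed": config.seed,
        "stage_seeds": {"balance": seeds[0], "split": seeds[1],
                        "tune": seeds[2], "fit": seeds[3]},
        "funnel": funnel,
        "files": sorted(p.name for p in paths.values()),
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReportBundle(
        out_dir=out,
        metrics=metrics,
        tune_result=tuned,
        importance=imp,
        category_importance=cat_imp,
        subgroup=subgroups,
        rates_by_group=rates_group,
        crosstab_frame=ct.to_frame(),
        decomposition=deco,
        manifest=manifest,
        paths=paths,
    )
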