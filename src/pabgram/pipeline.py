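"""End-to-end pipeline orchestration.

Stages (in dependency order): ``simulate`` → ``label`` → ``featurize`` →
``train`` → ``allocate`` → ``sweep`` → ``stats`` → ``ipw`` → ``report``.
Each stage reads the previous stages' artifacts from the output directory,
writes its own (CSV/JSON/MTX, plus pickled model stores), and records
output hashes in ``manifest.json`` together with the per-stage seeds fanned
out from the single global seed — re-running with the same configuration
and seed reproduces every artifact byte for byte. Exclusion counts (e.g.
contaminant cultures dropped) are logged so cohort attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import allocation as alloc_mod
from . import stats as stats_mod
from .cohort import (
    GeneratorConfig,
    analysis_set,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .features import BagOfWordsFeaturizer
from .ipw import (
    PhenotypeRuleSet,
    assign_buckets,
    fit_propensity,
    ipw_roc,
    sensitivity_label_matrix,
)
from .labeling import (
    SusceptibilityLabelMatrix,
    build_label_matrix,
    drop_contaminant_cultures,
)
from .models import ModelSelectionPlan, desk_grids, fit_antibiogram_suite

logger = logging.getLogger(__name__)

STAGES = ("simulate", "label", "featurize", "train", "allocate", "sweep", "stats", "ipw", "report")

_DEPS = {
    "simulate": (),
    "label": ("simulate",),
    "featurize": ("simulate", "label"),
    "train": ("featurize", "label"),
    "allocate": ("train", "label", "simulate"),
    "sweep": ("allocate",),
    "stats": ("allocate",),
    "ipw": ("train", "featurize", "simulate"),
    "report": ("train", "allocate"),
}


@dataclass
class PipelineConfig:
    outdir: str = "pabgram_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    plan: dict = field(default_factory=dict)  # ModelSelectionPlan overrides
    grid_preset: str = "desk"  # "desk" | "default"
    sweep_pairs: list[tuple[str, str]] | None = None
    stats_reps: int = 10_000
    random_baseline_seed_offset: int = 7919

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if raw.get("sweep_pairs"):
            raw["sweep_pairs"] = [tuple(p) for p in raw["sweep_pairs"]]
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def generator_config(self) -> GeneratorConfig:
        raw = dict(self.generator)
        raw.setdefault("seed", self.stage_seed("simulate"))
        return GeneratorConfig.from_dict(raw)

    def selection_plan(self) -> ModelSelectionPlan:
        raw = dict(self.plan)
        raw.setdefault("seed", self.stage_seed("train"))
        if "grids" not in raw and self.grid_preset == "desk":
            raw["grids"] = desk_grids()
        for key in ("train_years", "validation_years", "test_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return ModelSelectionPlan(**raw)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stateful driver; see :func:`run_pipeline` for the one-shot entry point."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {"seed": config.seed, "stages": {}}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # -- manifest helpers -------------------------------------------------
    def _record(self, stage: str, outputs: list[Path]) -> None:
        deps = {
            d: self.manifest["stages"].get(d, {}).get("outputs", {})
            for d in _DEPS[stage]
        }
        self.manifest["stages"][stage] = {
            "seed": self.config.stage_seed(stage),
            "outputs": {str(p.relative_to(self.outdir)): _sha(p) for p in outputs},
            "input_hashes": {d: h for d, h in deps.items()},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _require(self, stage: str) -> None:
        for dep in _DEPS[stage]:
            if dep not in self.manifest["stages"]:
                raise RuntimeError(
                    f"stage {stage!r} requires outputs of stage {dep!r}; run it first"
                )

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config.generator_config()
        cohort = generate_cohort(cfg)
        cdir = self.outdir / "cohort"
        write_cohort(cohort, cdir, cfg)
        self._record("simulate", sorted(cdir.glob("*.csv")) + [cdir / "cohort_manifest.yaml"])

    def _load_cohort(self):
        return read_cohort(self.outdir / "cohort")

    def label(self) -> None:
        self._require("label")
        cohort = self._load_cohort()
        retained = analysis_set(cohort)
        logger.info("label: %d of %d admissions retained as positive-culture infections",
                    len(retained), len(cohort))
        cfg = self.config.generator_config()
        matrix = build_label_matrix(retained, cfg.antibiotics, cfg.rule_table)
        matrix.to_csv(self.outdir / "labels.csv", self.outdir / "label_provenance.csv")
        self._record("label", [self.outdir / "labels.csv", self.outdir / "label_provenance.csv"])

    def featurize(self) -> None:
        self._require("featurize")
        cohort = self._load_cohort()
        plan = self.config.selection_plan()
        retained_ids = set(pd.read_csv(self.outdir / "labels.csv")["infection_id"])
        train_lo, train_hi = plan.train_years
        training = [
            inf for inf in cohort
            if inf.infection_id in retained_ids and train_lo <= inf.year <= train_hi
        ]
        fz = BagOfWordsFeaturizer().fit(training)
        X = fz.transform(cohort)
        fz.vocabulary_.to_json(self.outdir / "vocabulary.json")
        scipy.io.mmwrite(self.outdir / "features.mtx", sp.coo_matrix(X))
        rows = pd.DataFrame({
            "infection_id": [inf.infection_id for inf in cohort],
            "year": [inf.year for inf in cohort],
            "clinician_selection": [inf.clinician_selection or "" for inf in cohort],
        })
        rows.to_csv(self.outdir / "feature_rows.csv", index=False)
        (self.outdir / "feature_columns.txt").write_text("\n".join(fz.feature_names_) + "\n")
        self._record("featurize", [
            self.outdir / "vocabulary.json", self.outdir / "features.mtx",
            self.outdir / "feature_rows.csv", self.outdir / "feature_columns.txt",
        ])

    def _load_features(self):
        X = sp.csr_matrix(scipy.io.mmread(self.outdir / "features.mtx"))
        rows = pd.read_csv(self.outdir / "feature_rows.csv", keep_default_na=False)
        return X, rows

    def _load_labels(self) -> SusceptibilityLabelMatrix:
        return SusceptibilityLabelMatrix.from_csv(
            self.outdir / "labels.csv", self.outdir / "label_provenance.csv"
        )

    def train(self) -> None:
        self._require("train")
        X, rows = self._load_features()
        labels = self._load_labels()
        keep = rows["infection_id"].isin(labels.labels.index).to_numpy()
        X_ret = X[keep]
        rows_ret = rows[keep].reset_index(drop=True)
        lab = labels.labels.loc[rows_ret["infection_id"]]
        plan = self.config.selection_plan()
        suite = fit_antibiogram_suite(X_ret, lab, rows_ret["year"].to_numpy(), plan)
        suite.metrics.to_csv(self.outdir / "model_metrics.csv")
        suite.phi_test.to_csv(self.outdir / "phi_test.csv", index_label="infection_id")
        with open(self.outdir / "models.pkl", "wb") as fh:
            pickle.dump(suite.models, fh)
        self._record("train", [
            self.outdir / "model_metrics.csv", self.outdir / "phi_test.csv",
            self.outdir / "models.pkl",
        ])

    def allocate(self) -> None:
        self._require("allocate")
        labels = self._load_labels()
        phi = pd.read_csv(self.outdir / "phi_test.csv", index_col="infection_id")
        _, rows = self._load_features()
        selections = list(labels.labels.columns)
        # restrict to test admissions given one of the modelled selections,
        # with fully resolved labels so any assignment is scoreable
        clin = rows.set_index("infection_id")["clinician_selection"]
        idx = phi.index
        usable = [
            i for i in idx
            if clin.get(i, "") in selections and not labels.labels.loc[i].isna().any()
        ]
        phi_u = phi.loc[usable]
        lab_u = labels.labels.loc[usable, selections]
        clin_u = clin.loc[usable]
        budgets = alloc_mod.clinician_budgets(clin_u, selections)
        problem = alloc_mod.AllocationProblem(
            phi=phi_u.to_numpy(), budgets=budgets, selections=selections
        )
        pa = alloc_mod.solve_allocation(problem)
        clin_alloc = alloc_mod.clinician_allocation(clin_u, selections)
        rand = alloc_mod.random_allocation(
            budgets, seed=self.config.stage_seed("allocate"), selections=selections
        )
        result = {
            "n": len(usable),
            "budgets": {s: int(k) for s, k in zip(selections, budgets)},
            "pa_coverage": alloc_mod.coverage_rate(pa, lab_u),
            "clinician_coverage": alloc_mod.coverage_rate(clin_alloc, lab_u),
            "random_coverage": alloc_mod.coverage_rate(rand, lab_u),
            "pa_objective": pa.objective,
        }
        pd.DataFrame({
            "infection_id": usable,
            "pa_selection": [selections[j] for j in pa.assignment],
            "clinician_selection": clin_u.to_numpy(),
            "random_selection": [selections[j] for j in rand.assignment],
        }).to_csv(self.outdir / "allocations.csv", index=False)
        (self.outdir / "allocation_summary.json").write_text(json.dumps(result, indent=1))
        self._record("allocate", [self.outdir / "allocations.csv",
                                  self.outdir / "allocation_summary.json"])

    def _allocation_inputs(self):
        summary = json.loads((self.outdir / "allocation_summary.json").read_text())
        labels = self._load_labels()
        alloc_df = pd.read_csv(self.outdir / "allocations.csv")
        phi = pd.read_csv(self.outdir / "phi_test.csv", index_col="infection_id")
        usable = alloc_df["infection_id"].tolist()
        selections = list(labels.labels.columns)
        budgets = np.array([summary["budgets"][s] for s in selections])
        return summary, labels, alloc_df, phi.loc[usable], usable, selections, budgets

    def sweep(self) -> None:
        self._require("sweep")
        summary, labels, alloc_df, phi_u, usable, selections, budgets = self._allocation_inputs()
        lab_u = labels.labels.loc[usable, selections]
        problem = alloc_mod.AllocationProblem(
            phi=phi_u.to_numpy(), budgets=budgets, selections=selections
        )
        pairs = self.config.sweep_pairs
        if pairs is None:
            # default: the broadest budget-carrying selection into its
            # highest-prevalence single component
            order = lab_u.mean().sort_values(ascending=False).index
            broad = next(s for s in order if summary["budgets"][s] > 0 and " + " in s)
            narrow = max(
                (c for c in broad.split(" + ")), key=lambda c: lab_u[c].mean()
            )
            pairs = [(broad, narrow)]
        outputs = []
        for broad, narrow in pairs:
            res = alloc_mod.budget_sweep(
                problem, lab_u, (broad, narrow),
                clinician_rate=summary["clinician_coverage"],
                random_rate=summary["random_coverage"],
            )
            slug = f"{broad}__to__{narrow}".replace("/", "-").replace(" ", "_")
            path = self.outdir / f"sweep_{slug}.csv"
            res.curve.assign(broad=broad, narrow=narrow).to_csv(path, index=False)
            outputs.append(path)
        self._record("sweep", outputs)

    def stats(self) -> None:
        self._require("stats")
        summary, labels, alloc_df, phi_u, usable, selections, budgets = self._allocation_inputs()
        lab_u = labels.labels.loc[usable, selections]
        seed = self.config.stage_seed("stats")
        perm = stats_mod.permutation_test_vs_random(
            summary["pa_coverage"], lab_u, budgets, reps=self.config.stats_reps, seed=seed
        )
        clin_alloc = alloc_mod.clinician_allocation(
            alloc_df.set_index("infection_id").loc[usable, "clinician_selection"], selections
        )
        boot = stats_mod.stratified_bootstrap_vs_clinician(
            summary["pa_coverage"], clin_alloc, lab_u, reps=self.config.stats_reps, seed=seed + 1
        )
        out = {
            "pa_coverage": summary["pa_coverage"],
            "vs_random": {"p": perm.p_value, "p_str": perm.p_str, "floored": perm.p_floored,
                          "null": perm.null_quantiles},
            "vs_clinician": {"p": boot.p_value, "p_str": boot.p_str, "floored": boot.p_floored,
                             "null": boot.null_quantiles},
            "reps": self.config.stats_reps,
        }
        (self.outdir / "stats.json").write_text(json.dumps(out, indent=1))
        self._record("stats", [self.outdir / "stats.json"])

    def ipw(self) -> None:
        self._require("ipw")
        cohort = self._load_cohort()
        cohort = drop_contaminant_cultures(cohort)
        X, rows = self._load_features()
        keep = rows["infection_id"].isin({c.infection_id for c in cohort}).to_numpy()
        X, rows = X[keep], rows[keep].reset_index(drop=True)
        buckets = assign_buckets(cohort, PhenotypeRuleSet())
        buckets.table.to_csv(self.outdir / "buckets.csv")
        base = self._load_labels()
        cfg = self.config.generator_config()
        selections = [s.name for s in cfg.antibiotics]
        sens_labels = sensitivity_label_matrix(base, buckets, selections)
        order = rows["infection_id"]
        sens_lab = sens_labels.labels.loc[order]
        plan = self.config.selection_plan()
        suite = fit_antibiogram_suite(X, sens_lab, rows["year"].to_numpy(), plan)
        suite.metrics.to_csv(self.outdir / "sensitivity_model_metrics.csv")

        _, _, test_m = plan.split_masks(rows["year"].to_numpy())
        obs = buckets.observed.loc[order].to_numpy()
        propensity = fit_propensity(X, obs, seed=self.config.stage_seed("ipw"))
        table = []
        orig = pd.read_csv(self.outdir / "model_metrics.csv", index_col="selection")
        for sel in selections:
            y = sens_lab[sel].to_numpy(dtype=float)
            mask = test_m & obs & ~np.isnan(y)
            scores = suite.models[sel].predict_proba(X[mask])[:, 1]
            curve = ipw_roc(scores, y[mask], propensity[mask])
            table.append({
                "selection": sel,
                "original_auroc": float(orig.loc[sel, "auroc"]),
                "sensitivity_auroc": float(suite.metrics.loc[sel, "auroc"]),
                "ipw_auroc": curve.auroc,
            })
            slug = sel.replace("/", "-").replace(" ", "_")
            curve.as_frame().to_csv(self.outdir / f"ipw_curve_{slug}.csv", index=False)
        pd.DataFrame(table).set_index("selection").to_csv(self.outdir / "ipw_summary.csv")
        self._record("ipw", [self.outdir / "buckets.csv",
                             self.outdir / "sensitivity_model_metrics.csv",
                             self.outdir / "ipw_summary.csv"]
                     + sorted(self.outdir.glob("ipw_curve_*.csv")))

    def report(self) -> None:
        self._require("report")
        build_report(self.outdir)
        outputs = [self.outdir / "report.md"]
        outputs += self._plots()
        self._record("report", outputs)

    def _plots(self) -> list[Path]:
        """Best-effort sweep plots; skipped when matplotlib is absent."""
        try:
            from .plotting import plot_sweep_curve
        except ImportError:  # pragma: no cover
            return []
        summary_path = self.outdir / "allocation_summary.json"
        if not summary_path.exists():
            return []
        summary = json.loads(summary_path.read_text())
        written = []
        for p in sorted(self.outdir.glob("sweep_*.csv")):
            curve = pd.read_csv(p)
            title = f"{curve['broad'].iloc[0]} → {curve['narrow'].iloc[0]}"
            written.append(plot_sweep_curve(
                curve, summary["clinician_coverage"], summary["random_coverage"],
                p.with_suffix(".png"), title=title,
            ))
        return written

    def run(self, stages: tuple[str, ...] | None = None) -> dict:
        wanted = stages if stages is not None else self.config.stages
        for stage in STAGES:
            if stage in wanted:
                logger.info("running stage %s", stage)
                getattr(self, stage)()
        return self.manifest


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    return PipelineRun(config).run(stages)


def build_report(outdir: str | Path) -> str:
    """Assemble report.md from stage artifacts, without recomputation."""
    outdir = Path(outdir)
    parts = ["# Personalized antibiogram run report\n"]
    mm = outdir / "model_metrics.csv"
    if mm.exists():
        parts.append("## Susceptibility classifier performance (test set)\n")
        parts.append(pd.read_csv(mm).to_string(index=False))
    asummary = outdir / "allocation_summary.json"
    if asummary.exists():
        s = json.loads(asummary.read_text())
        parts.append("\n## Budget-constrained allocation\n")
        parts.append(
            f"- admissions allocated: {s['n']}\n"
            f"- personalized antibiogram coverage: {100 * s['pa_coverage']:.1f}%\n"
            f"- clinician coverage: {100 * s['clinician_coverage']:.1f}%\n"
            f"- random-baseline coverage: {100 * s['random_coverage']:.1f}%"
        )
    st = outdir / "stats.json"
    if st.exists():
        s = json.loads(st.read_text())
        parts.append(
            f"- p vs random: {s['vs_random']['p_str']}; "
            f"p vs clinician: {s['vs_clinician']['p_str']}"
        )
    sweeps = sorted(outdir.glob("sweep_*.csv"))
    if sweeps:
        parts.append("\n## Broad-to-narrow budget sweeps\n")
        for p in sweeps:
            df = pd.read_csv(p)
            ok = df[df["coverage"] >= json.loads(asummary.read_text())["clinician_coverage"]]
            pct = ok["percent_narrowed"].max() if len(ok) else 0.0
            parts.append(
                f"- {df['broad'].iloc[0]} → {df['narrow'].iloc[0]}: up to "
                f"{pct:.0f}% narrowed without dropping below the clinician coverage rate"
            )
    ipw_summary = outdir / "ipw_summary.csv"
    if ipw_summary.exists():
        parts.append("\n## Sensitivity analysis (censored labels, IPW)\n")
        parts.append(pd.read_csv(ipw_summary).to_string(index=False))
    text = "\n".join(parts) + "\n"
    (outdir / "report.md").write_text(text)
    return text
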