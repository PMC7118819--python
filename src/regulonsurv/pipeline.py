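"""End-to-end orchestration: simulate/load -> infer -> regulons -> score ->
train -> validate -> report, with provenance logging and a hashed manifest.

Every artifact a run writes is listed in ``manifest.json`` with a SHA-256
content hash, so two runs from the same (config, seed) can be compared
hash-for-hash.  All randomness flows from one root seed through named
per-stage substreams, which keeps each stage independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats as io
from .activity_scoring import (
    ActivityMatrix,
    score_activity_matrix,
    standardize_activities,
    write_activity_matrix,
)
from .cohort_analysis import anova_by_stage, cluster_activity
from .grn_inference import BoostingParams, infer_importances, write_importances
from .io_formats import ExpressionMatrix, SurvivalTable
from .regulon_builder import Regulon, build_regulons, select_top_pairs
from .survival_modeling import (
    RiskModel,
    assign_risk_groups,
    compute_risk_scores,
    fit_risk_model,
    km_curve,
    logrank_test,
    univariate_screen,
    write_screen_results,
)
from .synthetic_cohort import CohortConfig, apply_platform_transform, generate_cohort

log = logging.getLogger("regulonsurv")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_cohort", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return int(
        np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults follow the method's stated constants
    (top 5% of pairs, AUC rank cutoff 0.2, median risk-score split, p < 0.05)."""

    # input: either a synthetic cohort section or file paths
    synthetic: CohortConfig | None = None
    expression_path: str | None = None
    targets_path: str | None = None
    targets_format: str = "tsv2col"
    clinical_path: str | None = None

    # co-expression inference
    grn_mode: str = "boosting"  # or "spearman" (fast mode)
    grn_params: BoostingParams = field(default_factory=BoostingParams)

    # regulon refinement
    top_fraction: float = 0.05
    top_scope: str = "global"
    min_regulon_size: int = 10

    # activity scoring
    auc_cutoff: float = 0.2
    min_present_fraction: float = 0.8

    # survival modeling
    screen_alpha: float = 0.05
    ties: str = "efron"
    ridge: float = 0.0
    cutoff_policy: str = "median"

    # validation (synthetic mode)
    n_validation_cohorts: int = 1
    validation_transform: str = "affine"  # "none" | "affine" | "monotone_spline"

    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and not (
            self.expression_path and self.targets_path and self.clinical_path
        ):
            raise ValueError(
                "config needs either a synthetic section or expression/targets/clinical paths"
            )
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0.0 < self.auc_cutoff < 1.0:
            raise ValueError("auc_cutoff must be in (0, 1)")
        if not 0.0 < self.screen_alpha <= 1.0:
            raise ValueError("screen_alpha must be in (0, 1]")
        if self.validation_transform not in ("none", "affine", "monotone_spline"):
            raise ValueError(f"unknown validation transform {self.validation_transform!r}")
        if self.synthetic is not None:
            self.synthetic.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = doc.pop("synthetic", None)
        grn = doc.pop("grn_params", None)
        config = cls(**doc)
        if synthetic is not None:
            config.synthetic = CohortConfig(**synthetic)
        if grn is not None:
            config.grn_params = BoostingParams(**grn)
        config.validate()
        return config

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[str] = []
        self.handler = logging.FileHandler(outdir / "run.log", mode="w")
        self.handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(self.handler)
        log.setLevel(logging.INFO)

    def register(self, path: Path) -> Path:
        self.artifacts.append(str(path.relative_to(self.outdir)))
        return path

    def manifest(self, config: PipelineConfig, status: str) -> dict:
        return {
            "status": status,
            "seed": config.seed,
            "artifacts": {
                name: _sha256(self.outdir / name) for name in sorted(self.artifacts)
            },
        }

    def close(self) -> None:
        log.removeHandler(self.handler)
        self.handler.close()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and return the artifact manifest."""
    config.validate()
    outdir = Path(outdir)
    run = _Run(outdir)
    stage = "setup"
    try:
        log.info("pipeline config: %s", json.dumps(config.to_dict(), default=str))
        # -- inputs ---------------------------------------------------------
        stage = "simulate" if config.synthetic else "load"
        if config.synthetic:
            sim_cfg = dataclasses.replace(
                config.synthetic, seed=stage_seed(config.seed, "simulate")
            )
            expr, survival, target_map, truth = generate_cohort(sim_cfg)
            io.write_expression_matrix(expr, run.register(outdir / "expression.tsv"))
            io.write_survival_table(survival, run.register(outdir / "clinical.tsv"))
            io.write_target_map(target_map, run.register(outdir / "chip_targets.tsv"))
        else:
            expr = io.read_expression_matrix(config.expression_path)
            survival = io.read_survival_table(config.clinical_path)
            target_map = io.read_target_map(config.targets_path, format=config.targets_format)
            truth = None
        regulators = [r for r in target_map.regulators if r in set(expr.gene_ids)]
        absent = len(target_map) - len(regulators)
        if absent:
            log.info("%d regulators absent from the expression matrix; ignored", absent)

        # -- co-expression inference ---------------------------------------
        stage = "infer"
        importances = infer_importances(
            expr, regulators, params=config.grn_params,
            seed=stage_seed(config.seed, "grn"), mode=config.grn_mode,
        )
        write_importances(importances, run.register(outdir / "importances.tsv"))

        # -- regulon refinement --------------------------------------------
        stage = "regulons"
        pairs = select_top_pairs(importances, config.top_fraction, scope=config.top_scope)
        regulons = build_regulons(pairs, target_map, min_size=config.min_regulon_size)
        if not regulons:
            raise ValueError("no regulon survives the top-fraction/ChIP intersection")
        io.write_regulons_gmt(regulons, run.register(outdir / "regulons.gmt"))
        _write_provenance(regulons, run.register(outdir / "regulon_provenance.tsv"))

        # -- activity scoring ----------------------------------------------
        stage = "score"
        activity = score_activity_matrix(
            expr, regulons, cutoff_fraction=config.auc_cutoff,
            min_present_fraction=config.min_present_fraction,
        )
        write_activity_matrix(activity, run.register(outdir / "activity.tsv"))
        z = standardize_activities(activity)
        z.to_csv(run.register(outdir / "activity_z.tsv"), sep="\t", float_format="%.10g")

        # -- clustering ----------------------------------------------------
        stage = "cluster"
        report: dict = {}
        if z.shape[0] >= 2 and z.shape[1] >= 2:
            layout = cluster_activity(z)
            orders = outdir / "cluster_orders.tsv"
            with open(run.register(orders), "w") as fh:
                fh.write("axis\torder\n")
                fh.write("regulators\t" + ",".join(layout.ordered_rows()) + "\n")
                fh.write("samples\t" + ",".join(layout.ordered_cols()) + "\n")
            if config.make_plots:
                _plot_heatmap(z, layout, run.register(outdir / "activity_heatmap.png"))

        # -- survival screening and risk model -----------------------------
        stage = "train"
        screened = univariate_screen(
            activity, survival, alpha=config.screen_alpha, ties=config.ties
        )
        write_screen_results(screened, run.register(outdir / "screening.tsv"))
        if not screened:
            raise ValueError(
                f"no regulator passes the univariate screen at alpha={config.screen_alpha}"
            )
        model = fit_risk_model(
            activity, survival, [r.regulator for r in screened],
            ties=config.ties, ridge=config.ridge,
        )
        model.cutoff_policy = config.cutoff_policy
        model.to_json(run.register(outdir / "risk_model.json"))

        scores = compute_risk_scores(model, activity)
        assignment = assign_risk_groups(scores, cutoff=config.cutoff_policy)
        assignment.to_frame().to_csv(
            run.register(outdir / "risk_assignment.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        train_report = _survival_report(
            assignment, survival, outdir, run, prefix="training", plots=config.make_plots
        )
        report["training"] = train_report

        # -- stage ANOVA ---------------------------------------------------
        stage = "anova"
        if survival.stage is not None:
            surv_scored = survival.align(list(scores.index))
            try:
                f_stat, p, means = anova_by_stage(scores, surv_scored.stage)
                report["anova"] = {"F": f_stat, "p": p, "group_means": means}
            except ValueError as exc:
                log.warning("stage ANOVA skipped: %s", exc)

        # -- validation cohorts --------------------------------------------
        stage = "validate"
        if config.synthetic and config.n_validation_cohorts > 0:
            report["validation"] = []
            for i in range(config.n_validation_cohorts):
                vseed = stage_seed(config.seed, f"validation{i}")
                v_cfg = dataclasses.replace(config.synthetic, seed=vseed)
                v_expr, v_surv, _, _ = generate_cohort(v_cfg)
                if config.validation_transform != "none":
                    v_expr = apply_platform_transform(
                        v_expr, config.validation_transform,
                        seed=stage_seed(config.seed, f"platform{i}"),
                    )
                v_report = _validate(
                    model, regulons, v_expr, v_surv, config, outdir, run,
                    prefix=f"validation{i}",
                )
                report["validation"].append(v_report)

        stage = "report"
        report_path = run.register(outdir / "report.json")
        report_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
        manifest = run.manifest(config, "complete")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        if truth is not None:
            # ground truth kept outside the manifest: it is not a pipeline product
            _write_truth_summary(truth, activity, regulons, outdir)
        return manifest
    except Exception as exc:
        manifest = run.manifest(config, f"failed at {stage}")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc), manifest) from exc
    finally:
        run.close()


def _write_provenance(regulons: list[Regulon], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\tn_chip_targets\tn_top_pairs\tn_intersection\n")
        for r in regulons:
            fh.write(
                f"{r.regulator}\t{r.n_chip_targets}\t{r.n_top_pairs_for_regulator}"
                f"\t{r.n_intersection}\n"
            )


def _survival_report(
    assignment, survival: SurvivalTable, outdir: Path, run: _Run, prefix: str, plots: bool
) -> dict:
    surv = survival.align(assignment.sample_ids)
    groups = np.asarray(assignment.group)
    chi_square, p = logrank_test(groups, surv)
    curves = {}
    for label in ("low", "high"):
        mask = groups == label
        curve = km_curve(
            SurvivalTable(
                [s for s, m in zip(assignment.sample_ids, mask) if m],
                surv.time[mask], surv.event[mask],
            ),
            label=label,
        )
        curves[label] = curve
        curve.to_frame().to_csv(
            run.register(outdir / f"{prefix}_km_{label}.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
    if plots:
        _plot_km(curves, chi_square, p, run.register(outdir / f"{prefix}_km.png"))
    return {
        "n": int(len(groups)),
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
        "cutoff": float(assignment.cutoff),
        "logrank_chi_square": float(chi_square),
        "logrank_p": float(p),
    }


def _validate(
    model: RiskModel,
    regulons: list[Regulon],
    expr: ExpressionMatrix,
    survival: SurvivalTable,
    config: PipelineConfig,
    outdir: Path,
    run: _Run,
    prefix: str,
) -> dict:
    needed = [r for r in regulons if r.regulator in model.regulators]
    activity = score_activity_matrix(
        expr, needed, cutoff_fraction=config.auc_cutoff,
        min_present_fraction=config.min_present_fraction,
    )
    missing = [r for r in model.regulators if r not in activity.regulators]
    if missing:
        raise ValueError(f"validation cohort lacks required regulons: {missing}")
    scores = compute_risk_scores(model, activity)
    # per-cohort median split: the validation protocol recomputes the cutoff
    assignment = assign_risk_groups(scores, cutoff=model.cutoff_policy)
    assignment.to_frame().to_csv(
        run.register(outdir / f"{prefix}_risk_assignment.tsv"), sep="\t", index=False,
        float_format="%.10g",
    )
    return _survival_report(
        assignment, survival, outdir, run, prefix=prefix, plots=config.make_plots
    )


def _write_truth_summary(truth, activity: ActivityMatrix, regulons, outdir: Path) -> None:
    rows = []
    frame = activity.to_frame()
    for regulon in regulons:
        reg = regulon.regulator
        if reg not in truth.regulators or reg not in frame.index:
            continue
        est = frame.loc[reg].to_numpy(float)
        true = truth.activity_of(reg)
        ok = np.isfinite(est)
        corr = float(np.corrcoef(est[ok], true[ok])[0, 1]) if ok.sum() > 2 else float("nan")
        planted = truth.true_targets[reg]
        frac = len(regulon.targets & planted) / len(regulon.targets)
        rows.append((reg, corr, frac))
    with open(outdir / "truth_summary.tsv", "w") as fh:
        fh.write("regulator\tactivity_truth_correlation\tplanted_target_fraction\n")
        for reg, corr, frac in rows:
            fh.write(f"{reg}\t{corr:.6g}\t{frac:.6g}\n")


# ---------------------------------------------------------------------------
# standalone validation of an external cohort
# ---------------------------------------------------------------------------


def validate_cohort(
    model_path: str | Path,
    regulons_path: str | Path,
    expr_path: str | Path,
    clinical_path: str | Path,
    outdir: str | Path | None = None,
    auc_cutoff: float = 0.2,
    min_present_fraction: float = 0.8,
) -> dict:
    """Score an independent cohort with a frozen risk model.

    The cohort is split at its own median risk score and the high/low groups
    compared by the log-rank test.
    """
    model = RiskModel.from_json(model_path)
    target_map = io.read_target_map(regulons_path, format="gmt")
    expr = io.read_expression_matrix(expr_path)
    survival = io.read_survival_table(clinical_path)
    regulons = [
        Regulon(regulator=reg, targets=set(target_map.entries[reg]))
        for reg in target_map.regulators
        if reg in model.regulators
    ]
    missing = [r for r in model.regulators if r not in {x.regulator for x in regulons}]
    if missing:
        raise ValueError(f"regulon file lacks model regulators: {missing}")
    activity = score_activity_matrix(
        expr, regulons, cutoff_fraction=auc_cutoff,
        min_present_fraction=min_present_fraction,
    )
    lost = [r for r in model.regulators if r not in activity.regulators]
    if lost:
        raise ValueError(f"validation cohort lacks required regulon genes for: {lost}")
    scores = compute_risk_scores(model, activity)
    common = [s for s in scores.index if s in set(survival.sample_ids)]
    scores = scores[common]
    assignment = assign_risk_groups(scores, cutoff=model.cutoff_policy)
    surv = survival.align(assignment.sample_ids)
    chi_square, p = logrank_test(np.asarray(assignment.group), surv)
    report = {
        "n": len(common),
        "cutoff": float(assignment.cutoff),
        "logrank_chi_square": float(chi_square),
        "logrank_p": float(p),
        "risk_groups": dict(zip(assignment.sample_ids, assignment.group)),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignment.to_frame().to_csv(
            outdir / "validation_risk_assignment.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        summary = {k: v for k, v in report.items() if k != "risk_groups"}
        (outdir / "validation_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return report


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def _plot_km(curves: dict, chi_square: float, p: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"low": "tab:blue", "high": "tab:red"}
    for label, curve in curves.items():
        ax.step(curve.times, curve.survival_prob, where="post",
                label=f"{label} risk", color=colors.get(label))
        if len(curve.censor_times):
            probs = [curve.at(t) for t in curve.censor_times]
            ax.plot(curve.censor_times, probs, "|", color=colors.get(label), ms=8)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left")
    ax.set_title(f"log-rank p = {p:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_heatmap(z, layout, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = z.iloc[layout.row_order, layout.col_order]
    lim = float(np.nanmax(np.abs(ordered.to_numpy())))
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-lim, vmax=lim)
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel("samples (clustered)")
    fig.colorbar(im, ax=ax, label="activity z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
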