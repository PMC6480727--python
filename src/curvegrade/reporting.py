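"""Response curves, table rendering and end-to-end pipeline orchestration.

The pipeline mirrors the original analysis sequence: (optionally simulate
a cohort) -> descriptive moments with Fisher CIs -> one-factor g scoring
-> rescaling of the four predictors to center 3 / SD 1 -> linear baselines
for all four grades -> drop the sports grade -> polynomial grid searches
with the g score alone and with the three specific tests for each
remaining grade -> best-model comparison table -> response curves of the
selected models.  Every artifact is a plain-text table (TSV/CSV/JSON) and
the manifest records a SHA-256 per file, so identical configuration and
seed reproduce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (
    MomentSummary,
    ScalingParams,
    TEST_VARIABLES,
    compute_moments,
    fisher_ci,
    read_cohort,
    scale_predictors,
    write_cohort,
)
from .errors import ConfigError, DataError, DomainError
from .factor import paf_one_factor
from .linear import RegressionResult, fit_from_moments, fit_ols
from .polysearch import (
    DegreeGrid,
    FittedPolyModel,
    FractionalPolySearch,
    ModelComparison,
    compare_models,
)
from .simulate import GenerativeSpec, default_generative_spec, generate_cohort

logger = logging.getLogger(__name__)

ACADEMIC_GRADES = ("grade_math", "grade_german", "grade_english")
ALL_GRADES = ACADEMIC_GRADES + ("grade_sports",)


# ---------------------------------------------------------------------------
# response curves


@dataclass
class ResponseCurve:
    """Model-implied grade as one predictor varies, others fixed.

    ``fixed_level`` defaults to 3, the center of the scaled predictor
    space, so the curve shows the marginal shape of one ability's relation
    with the grade at average levels of the others.
    """

    outcome: str
    varying_predictor: str
    grid_points: np.ndarray
    predicted: np.ndarray
    fixed_level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome": self.outcome,
                "predictor": self.varying_predictor,
                "x": self.grid_points,
                "predicted": self.predicted,
                "fixed_level": self.fixed_level,
            }
        )


def response_curve(
    model: FittedPolyModel,
    varying: str,
    lo: float = 1.0,
    hi: float = 5.0,
    resolution: int = 101,
    fixed_level: float = 3.0,
) -> ResponseCurve:
    """Evaluate a fitted model along one predictor (others held at 3).

    The default range 1..5 covers +/-2 SD around the scaled center while
    staying inside the positive domain required by fractional powers.
    """
    predictors = model.spec.predictors
    if varying not in predictors:
        raise ConfigError(f"{varying!r} is not a predictor of this model")
    if lo <= 0 and any(
        d != round(d) for d in model.spec.power_degrees
    ):
        raise DomainError("curve range includes non-positive values under fractional degrees")
    pts = np.linspace(lo, hi, resolution)
    x = np.full((resolution, len(predictors)), float(fixed_level))
    x[:, predictors.index(varying)] = pts
    return ResponseCurve(
        outcome=model.spec.outcome,
        varying_predictor=varying,
        grid_points=pts,
        predicted=model.predict(x),
        fixed_level=fixed_level,
    )


# ---------------------------------------------------------------------------
# table rendering


def render_moments_table(moments: MomentSummary) -> str:
    """Descriptive table: per-variable M/SD, correlations with Fisher CIs.

    Two-decimal values with the 95% CI in brackets beneath each
    correlation, mirroring conventional psychology reporting.
    """
    lines = ["variable\tM\tSD\t" + "\t".join(
        str(i + 1) for i in range(len(moments.variable_names) - 1)
    )]
    for i, name in enumerate(moments.variable_names):
        vals, cis = [], []
        for j in range(i):
            r = moments.corr[i, j]
            vals.append(f"{r:.2f}")
            if abs(r) < 1:
                lo, hi = fisher_ci(r, moments.n)
                cis.append(f"[{lo:.2f}, {hi:.2f}]")
            else:
                cis.append("")
        lines.append(
            f"{i + 1}. {name}\t{moments.means[i]:.2f}\t{moments.sds[i]:.2f}\t"
            + "\t".join(vals)
        )
        if vals:
            lines.append("\t\t\t" + "\t".join(cis))
    return "\n".join(lines) + "\n"


def render_baseline_table(results: Sequence[RegressionResult]) -> str:
    """Regression table: b, CI, beta, CI, sr2, r, R2, adjusted R2 per grade."""
    lines = [
        "subject\tpredictor\tb\tb_95ci\tbeta\tbeta_95ci\tsr2\tr\tR2\tadj_R2"
    ]
    for res in results:
        stars = res.stars()
        for j, p in enumerate(res.predictors):
            lines.append(
                f"{res.outcome}\t{p}\t{res.b[j]:.2f}{stars[j]}\t"
                f"[{res.b_ci[j, 0]:.2f}, {res.b_ci[j, 1]:.2f}]\t"
                f"{res.beta[j]:.2f}\t"
                f"[{res.beta_ci[j, 0]:.2f}, {res.beta_ci[j, 1]:.2f}]\t"
                f"{res.sr2[j]:.2f}\t{res.zero_order[j]:.2f}\t\t"
            )
        r2_star = "**" if res.r2_pvalue < 0.01 else "*" if res.r2_pvalue < 0.05 else ""
        ci = (
            f" 95% CI [{res.r2_ci[0]:.2f}, {res.r2_ci[1]:.2f}]"
            if res.r2_ci is not None
            else ""
        )
        lines.append(
            f"{res.outcome}\t\t\t\t\t\t\t\t{res.r2:.3f}{r2_star}{ci}\t{res.adj_r2:.3f}"
        )
    return "\n".join(lines) + "\n"


def render_comparison_table(comparisons: Sequence[ModelComparison]) -> str:
    """Best-model table: degrees, adjusted R2 and criterion per predictor set.

    The criterion column keeps the conventional "RMSE" label; it is the
    median absolute leave-one-out deviation.
    """
    lines = ["predictor_set\tcriterion_subject\tdegrees\tadj_R2\tRMSE"]
    for c in comparisons:
        lines.append(
            f"g_factor\t{c.outcome}\t"
            + ",".join(f"{d:g}" for d in c.g_degrees)
            + f"\t{c.g_adj_r2:.3f}\t{c.g_criterion:.3f}"
        )
    for c in comparisons:
        lines.append(
            f"specific_tests\t{c.outcome}\t"
            + ",".join(f"{d:g}" for d in c.specific_degrees)
            + f"\t{c.specific_adj_r2:.3f}\t{c.specific_criterion:.3f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``cohort_path`` (per-subject CSV), ``moments_path``
    (moment-summary JSON) or ``generative`` (a :class:`GenerativeSpec`,
    or the string ``"default"`` for the emulated study conditions) must
    be set.
    """

    output_dir: str | Path
    cohort_path: str | Path | None = None
    moments_path: str | Path | None = None
    generative: GenerativeSpec | str | None = None
    outcomes: tuple[str, ...] = ACADEMIC_GRADES
    grid: DegreeGrid = field(default_factory=DegreeGrid)
    seed: int = 0
    r2_ci_reps: int = 0
    #: policy for scaled predictor values <= 0: the pipeline clamps (and
    #: logs) by default so a single boundary subject does not abort a run;
    #: library-level scale_predictors keeps the hard error as its default.
    on_nonpositive: str = "clamp"

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.cohort_path, self.moments_path, self.generative) if s
        ]
        if len(sources) != 1:
            raise ConfigError("exactly one input source must be configured")
        if not self.outcomes:
            raise ConfigError("at least one outcome required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        gen = raw.get("generative")
        if isinstance(gen, Mapping):
            gen = GenerativeSpec.from_dict(gen)
        grid = raw.get("grid")
        if isinstance(grid, Mapping):
            grid = DegreeGrid.regular(
                step=float(grid.get("step", 0.5)),
                max_degree=float(grid.get("max_degree", 5.0)),
                include_linear=bool(grid.get("include_linear", True)),
            )
        elif isinstance(grid, Sequence) and not isinstance(grid, str):
            grid = DegreeGrid(tuple(float(v) for v in grid))
        else:
            grid = DegreeGrid()
        return cls(
            output_dir=raw["output_dir"],
            cohort_path=raw.get("cohort"),
            moments_path=raw.get("moments"),
            generative=gen,
            outcomes=tuple(raw.get("outcomes", ACADEMIC_GRADES)),
            grid=grid,
            seed=int(raw.get("seed", 0)),
            r2_ci_reps=int(raw.get("r2_ci_reps", 0)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def attach_g_scores(
    cohort: pd.DataFrame, on_nonpositive: str = "error"
) -> tuple[pd.DataFrame, object]:
    """Fit the one-factor model on the three tests and append g columns.

    Adds ``g`` (regression factor score, mean 0) and ``g_scaled``
    (rescaled to center 3 / SD 1) to a copy of the cohort.
    """
    moments = compute_moments(cohort, TEST_VARIABLES)
    solution = paf_one_factor(moments.subset(TEST_VARIABLES))
    out = cohort.copy()
    out["g"] = solution.scores(cohort)
    out, _ = scale_predictors(
        out.assign(g_scaled=out["g"]), ("g_scaled",), "fit",
        on_nonpositive=on_nonpositive,
    )
    return out, solution


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write an artifact bundle.

    Returns the manifest (also written to ``manifest.json``): every file
    with its SHA-256, plus a log of structural decisions (grid size,
    factor convergence, linear-model ranks).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []
    files: dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        path = out_dir / name
        _write(path, text)
        files[name] = _sha256(path)

    # --- stage 1: obtain the cohort (or moments only) ----------------------
    cohort: pd.DataFrame | None = None
    if config.generative is not None:
        spec = (
            default_generative_spec(seed=config.seed)
            if isinstance(config.generative, str)
            else config.generative
        )
        cohort = generate_cohort(spec)
        write_cohort(cohort, out_dir / "cohort.csv")
        files["cohort.csv"] = _sha256(out_dir / "cohort.csv")
        spec.to_json(out_dir / "generative_spec.json")
        files["generative_spec.json"] = _sha256(out_dir / "generative_spec.json")
        notes.append(f"simulated cohort: n={spec.n}, seed={spec.seed}")
    elif config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        notes.append(f"cohort loaded: n={len(cohort)}")

    if cohort is None:
        moments = MomentSummary.from_json(config.moments_path)
        notes.append(
            "moments-only input: raw data required for polynomial search; "
            "baselines only"
        )
        emit("moments.tsv", render_moments_table(moments))
        baselines = []
        for outcome in config.outcomes:
            for preds in (("g",), TEST_VARIABLES):
                try:
                    baselines.append(fit_from_moments(moments, outcome, preds))
                except Exception as exc:  # missing variable in summary
                    notes.append(f"baseline skipped ({outcome} ~ {preds}): {exc}")
        emit("baselines.tsv", render_baseline_table(baselines))
        manifest = {"files": files, "notes": notes, "seed": config.seed}
        _write(out_dir / "manifest.json", json.dumps(manifest, indent=1) + "\n")
        return manifest

    # --- stage 2: moments, g scoring, scaling ------------------------------
    grade_cols = [g for g in ALL_GRADES if g in cohort.columns]
    moments = compute_moments(cohort, TEST_VARIABLES + tuple(grade_cols))
    cohort, solution = attach_g_scores(cohort, on_nonpositive=config.on_nonpositive)
    notes.append(
        f"PAF converged in {solution.iterations} iterations; "
        f"eigenvalue {solution.eigenvalue:.4f}"
    )
    solution.to_json(out_dir / "factor_solution.json")
    files["factor_solution.json"] = _sha256(out_dir / "factor_solution.json")
    emit(
        "moments.tsv",
        render_moments_table(compute_moments(cohort, ("g",) + TEST_VARIABLES + tuple(grade_cols))),
    )
    scaled, scaling = scale_predictors(
        cohort, TEST_VARIABLES, "fit", on_nonpositive=config.on_nonpositive
    )
    notes.append(
        f"predictors scaled to center 3 / SD 1: {TEST_VARIABLES} "
        f"(nonpositive policy: {config.on_nonpositive})"
    )

    # --- stage 3: linear baselines (all grades incl. sports) ---------------
    baselines = []
    for outcome in grade_cols:
        baselines.append(
            fit_ols(cohort, outcome, ("g",), r2_ci_reps=config.r2_ci_reps,
                    seed=config.seed)
        )
        baselines.append(
            fit_ols(cohort, outcome, TEST_VARIABLES,
                    r2_ci_reps=config.r2_ci_reps, seed=config.seed)
        )
    emit("baselines.tsv", render_baseline_table(baselines))
    if "grade_sports" in grade_cols:
        notes.append("sports grade excluded from the polynomial search")

    # --- stage 4: polynomial searches --------------------------------------
    outcomes = [o for o in config.outcomes if o != "grade_sports" and o in cohort.columns]
    comparisons = []
    evaluations_dump = {}
    for outcome in outcomes:
        g_search = FractionalPolySearch(
            scaled.assign(**{outcome: cohort[outcome]}), outcome, ("g_scaled",),
            config.grid,
        ).fit()
        sp_search = FractionalPolySearch(
            scaled.assign(**{outcome: cohort[outcome]}), outcome, TEST_VARIABLES,
            config.grid,
        ).fit()
        notes.append(
            f"{outcome}: linear model rank {g_search.linear_rank}/"
            f"{len(g_search.ranking)} (g) and {sp_search.linear_rank}/"
            f"{len(sp_search.ranking)} (specific)"
        )
        comparisons.append(compare_models(g_search, sp_search))
        for tag, res in (("g", g_search), ("specific", sp_search)):
            evaluations_dump[f"{outcome}:{tag}"] = {
                "best": res.best.to_dict(),
                "linear_rank": res.linear_rank,
                "linear_criterion": res.linear_criterion,
            }
            res.to_frame().to_csv(
                out_dir / f"ranking_{outcome}_{tag}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            files[f"ranking_{outcome}_{tag}.tsv"] = _sha256(
                out_dir / f"ranking_{outcome}_{tag}.tsv"
            )
        # --- stage 5: response curves for the selected specific model ------
        curves = pd.concat(
            [
                response_curve(sp_search.best, var).to_frame()
                for var in TEST_VARIABLES
            ]
        )
        curves.to_csv(out_dir / f"curves_{outcome}.csv", index=False,
                      float_format="%.10g")
        files[f"curves_{outcome}.csv"] = _sha256(out_dir / f"curves_{outcome}.csv")

    emit("best_models.tsv", render_comparison_table(comparisons))
    _write(out_dir / "evaluations.json", json.dumps(evaluations_dump, indent=1) + "\n")
    files["evaluations.json"] = _sha256(out_dir / "evaluations.json")

    manifest = {"files": files, "notes": notes, "seed": config.seed,
                "grid_states": len(config.grid.values)}
    _write(out_dir / "manifest.json", json.dumps(manifest, indent=1) + "\n")
    return manifest
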