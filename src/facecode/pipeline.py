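"""End-to-end orchestration: simulate -> measures -> stats -> cross-validation.

``run_pipeline`` executes the full analysis battery on a cohort — Pearson
correlations between each neural measure and each behavioral score,
dependent-correlation (Steiger/MRR) comparisons for the double
dissociation, covariate-adjusted multiple regressions, gender contrasts,
and balanced-fold cross-validated prediction with a permutation null —
and writes tidy CSV tables plus a human-readable report. Every random
stage draws from seeds spawned deterministically from the run seed, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval, io, roi, stats
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "make_report",
           "measures_table"]

MEASURE_COLUMNS = ("selectivity", "dissim_between", "dissim_within")

DEFAULT_ANALYSIS_PAIRS = (
    ("selectivity", "eyes_score"),
    ("dissim_between", "eyes_score"),
    ("selectivity", "face_acc"),
    ("dissim_between", "face_acc"),
)

DEFAULT_REGRESSIONS = (
    ("eyes_score", ("dissim_between", "selectivity", "gender")),
    ("face_acc", ("dissim_between", "selectivity", "flower_acc", "gender")),
    ("face_acc", ("dissim_between", "dissim_within")),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "synthetic"                  # synthetic | patterns-csv
    sim: SimConfig = field(default_factory=SimConfig)
    patterns_dir: str | None = None          # for patterns-csv mode
    subjects_csv: str | None = None
    analysis_pairs: tuple[tuple[str, str], ...] = DEFAULT_ANALYSIS_PAIRS
    regressions: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_REGRESSIONS
    centering_categories: tuple[str, ...] | None = roi.DEFAULT_CATEGORIES
    k_folds: int = 4
    n_permutations: int = 5000
    balance_alpha: float = 0.05
    seed: int = 0
    output_dir: str = "facecode_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        pairs = raw.pop("analysis_pairs", None)
        regs = raw.pop("regressions", None)
        kwargs = dict(raw, sim=sim)
        if pairs is not None:
            kwargs["analysis_pairs"] = tuple(tuple(p) for p in pairs)
        if regs is not None:
            kwargs["regressions"] = tuple(
                (resp, tuple(preds)) for resp, preds in regs
            )
        return cls(**kwargs)

    def validate(self, n_subjects: int, columns) -> None:
        if n_subjects < 2 * self.k_folds:
            raise ValueError(
                f"n_subjects={n_subjects} below 2*k={2 * self.k_folds}: too few "
                "subjects for balanced folds"
            )
        referenced = {c for pair in self.analysis_pairs for c in pair}
        for resp, preds in self.regressions:
            referenced |= {resp, *preds}
        missing = referenced - set(columns) - set(MEASURE_COLUMNS)
        if missing:
            raise ValueError(f"configured columns not in the subject table: "
                             f"{sorted(missing)}")


@dataclass
class AnalysisReport:
    subjects: pd.DataFrame
    correlations: pd.DataFrame
    steiger: pd.DataFrame
    regressions: pd.DataFrame
    gender_tests: pd.DataFrame
    crossval: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict


def measures_table(
    subjects: pd.DataFrame,
    patterns,
    centering_categories=roi.DEFAULT_CATEGORIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append the three neural measures to the subject table.

    Subjects whose patterns cannot yield a measure (ROI not identified /
    too few voxels) go to the exclusion log instead; returns
    (analyzed table, exclusion log). Analyzed + excluded = input.
    """
    rows, excl = [], []
    for (_, rec), pat in zip(subjects.iterrows(), patterns):
        rec = rec.to_dict()
        if pat is None or pat.n_voxels < 2:
            excl.append({"subject_id": rec["subject_id"],
                         "reason": "ROI not identified"
                         if pat is None else "ROI smaller than 2 voxels"})
            continue
        m = roi.compute_measures(pat, centering_categories=centering_categories)
        rec["selectivity"] = m.overall_selectivity
        rec["dissim_between"] = m.between_dissimilarity
        rec["dissim_within"] = m.within_dissimilarity
        rows.append(rec)
    excl_df = pd.DataFrame(excl, columns=["subject_id", "reason"])
    return pd.DataFrame(rows), excl_df


def _correlation_table(df: pd.DataFrame, pairs) -> pd.DataFrame:
    rows = []
    for xcol, ycol in pairs:
        res = stats.pearson_with_p(df[xcol], df[ycol])
        rows.append({"x": xcol, "y": ycol, "n": res.n, "r": res.r,
                     "p_two_tailed": res.p_two_tailed})
    return pd.DataFrame(rows)


def _steiger_table(df: pd.DataFrame) -> pd.DataFrame:
    """The two planned dependent-correlation comparisons.

    For each behavior, compare its correlation with the 'matching' measure
    against its correlation with the other measure; r23 is the correlation
    between the two neural measures.
    """
    r23 = stats.pearson_with_p(df["selectivity"], df["dissim_between"]).r
    n = len(df)
    rows = []
    for behavior, primary, secondary in (
        ("eyes_score", "selectivity", "dissim_between"),
        ("face_acc", "dissim_between", "selectivity"),
    ):
        r12 = stats.pearson_with_p(df[behavior], df[primary]).r
        r13 = stats.pearson_with_p(df[behavior], df[secondary]).r
        cmp_ = stats.steiger_z(r12, r13, r23, n)
        rows.append({"behavior": behavior, "primary": primary,
                     "secondary": secondary, "r12": r12, "r13": r13,
                     "r23": r23, "n": n, "z": cmp_.z,
                     "p_one_tailed": cmp_.p_one_tailed})
    return pd.DataFrame(rows)


def _regression_table(df: pd.DataFrame, regressions) -> pd.DataFrame:
    frames = []
    for i, (resp, preds) in enumerate(regressions, start=1):
        tab = stats.ols_regression(df[resp], df[list(preds)])
        tab.insert(0, "model", i)
        tab.insert(1, "response", resp)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _gender_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in ("face_acc", "flower_acc", "eyes_score"):
        res = stats.two_group_test(df[col].to_numpy(float), df["gender"])
        rows.append({"score": col, "t": res.t, "p_two_tailed": res.p_two_tailed,
                     "cohens_d": res.cohens_d, "n_male": res.n0,
                     "n_female": res.n1})
    return pd.DataFrame(rows)


def _crossval_table(df: pd.DataFrame, pairs, k, B, balance_alpha,
                    seeds) -> pd.DataFrame:
    rows = []
    for (xcol, ycol), seed_pair in zip(pairs, seeds):
        x = df[xcol].to_numpy(float)
        y = df[ycol].to_numpy(float)
        folds = crossval.balanced_folds(x, y, k=k, balance_alpha=balance_alpha,
                                        seed=int(seed_pair[0]))
        res = crossval.cv_predict(x, y, folds)
        p = crossval.permutation_p(x, y, folds, B=B, seed=int(seed_pair[1]))
        rows.append({"x": xcol, "y": ycol, "n": x.size, "k": k,
                     "r_prediction_observation": res.r_prediction_observation,
                     "p_permutation": p, "B": B,
                     "fold_seed": int(seed_pair[0]),
                     "perm_seed": int(seed_pair[1]),
                     "balance_p_x": folds.p_x, "balance_p_y": folds.p_y})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write: bool = True) -> AnalysisReport:
    """Execute every configured stage and (optionally) write the bundle."""
    rng_root = np.random.SeedSequence(config.seed)
    cohort_seed, *cv_entropy = rng_root.spawn(1 + 2 * len(config.analysis_pairs))

    if config.mode == "synthetic":
        sim = dataclasses.replace(
            config.sim, seed=int(cohort_seed.generate_state(1)[0] % (2 ** 31))
        )
        subjects, patterns, _ = generate_cohort(sim)
    elif config.mode == "patterns-csv":
        if not (config.subjects_csv and config.patterns_dir):
            raise ValueError("patterns-csv mode needs subjects_csv and patterns_dir")
        subjects = io.read_subject_table(config.subjects_csv)
        patterns = io.read_cohort_patterns(subjects["subject_id"], config.patterns_dir)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    config.validate(len(subjects), subjects.columns)
    analyzed, exclusions = measures_table(
        subjects, patterns, centering_categories=config.centering_categories
    )
    if len(analyzed) + len(exclusions) != len(subjects):
        raise AssertionError("subject count not conserved across the measure stage")

    cv_seeds = [
        (s.generate_state(1)[0] % (2 ** 31), t.generate_state(1)[0] % (2 ** 31))
        for s, t in zip(cv_entropy[0::2], cv_entropy[1::2])
    ]
    report = AnalysisReport(
        subjects=analyzed,
        correlations=_correlation_table(analyzed, config.analysis_pairs),
        steiger=_steiger_table(analyzed),
        regressions=_regression_table(analyzed, config.regressions),
        gender_tests=_gender_table(analyzed),
        crossval=_crossval_table(analyzed, config.analysis_pairs, config.k_folds,
                                 config.n_permutations, config.balance_alpha,
                                 cv_seeds),
        exclusions=exclusions,
        manifest={
            "seed": config.seed,
            "mode": config.mode,
            "k_folds": config.k_folds,
            "n_permutations": config.n_permutations,
            "n_subjects_input": int(len(subjects)),
            "n_analyzed": int(len(analyzed)),
            "n_excluded": int(len(exclusions)),
            "centering_categories": list(config.centering_categories or []),
        },
    )
    if write:
        _write_bundle(report, config)
    return report


def _write_bundle(report: AnalysisReport, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.subjects.to_csv(out / "subjects.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.steiger.to_csv(out / "steiger.csv", index=False)
    report.regressions.to_csv(out / "regressions.csv", index=False)
    report.gender_tests.to_csv(out / "gender_tests.csv", index=False)
    report.crossval.to_csv(out / "crossval.csv", index=False)
    report.exclusions.to_csv(out / "exclusions.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(make_report(report))


def _fmt_float(v) -> str:
    return f"{v:.4g}" if isinstance(v, float) else str(v)


def make_report(report: AnalysisReport) -> str:
    """Human-readable text bundle mirroring the analysis battery's tables."""
    for name in ("correlations", "steiger", "regressions", "crossval"):
        tab = getattr(report, name)
        if tab is None or len(tab) == 0:
            raise ValueError(f"cannot render report: {name} table is missing or empty")
    lines = ["facecode analysis report", "=" * 40, ""]
    lines += [f"subjects analyzed: {report.manifest['n_analyzed']}"
              f" (excluded: {report.manifest['n_excluded']})", ""]

    lines += ["Correlations (measure x behavior)", "-" * 40]
    for _, r in report.correlations.iterrows():
        lines.append(f"  r({r['x']}, {r['y']}) = {r['r']:.3f}  "
                     f"p = {r['p_two_tailed']:.4g}  (n = {r['n']})")
    lines.append("")

    lines += ["Dependent-correlation comparisons", "-" * 40]
    for _, r in report.steiger.iterrows():
        lines.append(
            f"  {r['behavior']}: r({r['primary']}) = {r['r12']:.3f} vs "
            f"r({r['secondary']}) = {r['r13']:.3f}  ->  Z = {r['z']:.2f}, "
            f"one-tail p = {r['p_one_tailed']:.3g}"
        )
    lines.append("")

    lines += ["Multiple regressions (beta, SE beta, standardized beta, p)",
              "-" * 40]
    for (model, resp), grp in report.regressions.groupby(["model", "response"],
                                                         sort=False):
        lines.append(f"  model {model} — response: {resp}")
        for _, r in grp.iterrows():
            sb = "" if np.isnan(r["standardized_beta"]) else \
                f"  std beta = {r['standardized_beta']:.3f}"
            lines.append(f"    {r['predictor']:<16} beta = {r['beta']:.4g}  "
                         f"SE = {r['se_beta']:.4g}{sb}  p = {r['p']:.4g}")
    lines.append("")

    lines += ["Gender contrasts", "-" * 40]
    for _, r in report.gender_tests.iterrows():
        lines.append(f"  {r['score']}: t = {r['t']:.2f}, p = "
                     f"{r['p_two_tailed']:.4g}, d = {r['cohens_d']:.2f}")
    lines.append("")

    lines += ["Cross-validated prediction", "-" * 40]
    for _, r in report.crossval.iterrows():
        lines.append(
            f"  {r['x']} -> {r['y']}: r(prediction, observation) = "
            f"{r['r_prediction_observation']:.3f}, permutation p = "
            f"{r['p_permutation']:.4g} (B = {r['B']})"
        )
    lines.append("")
    return "\n".join(lines)
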