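"""End-to-end pipeline: simulate (or load) -> preprocess -> components ->
laterality -> molecular correlation -> group statistics -> report.

Subjects are processed one at a time in simulate mode (generate epochs,
preprocess, measure, discard) so full cohorts with hundreds of trials per
condition never hold the whole trial-level array in memory.  All outputs
are delimited text tables with a comment-line run manifest (seed, config
hash, package version); row order is deterministic.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .components import ComponentExtractor
from .config import PipelineConfig
from .epochs import Epochs
from .laterality import (LateralityScorer, cohort_summary,
                         sensitivity_t_tests)
from .molecular import correlate_grid, zscore_within_batch
from .preprocess import preprocess_epochs
from .simulate import CohortSimulator
from .stats import anova_table, chi_square_2x2, mixed_anova

log = logging.getLogger("motionlat")


@dataclasses.dataclass
class ResultsBundle:
    truth: pd.DataFrame | None
    rejection_summary: pd.DataFrame
    components: pd.DataFrame
    laterality: pd.DataFrame
    sensitivity_tests: pd.DataFrame
    correlations: pd.DataFrame | None
    anova: pd.DataFrame
    chi_square: pd.DataFrame
    summary: "object"
    manifest: dict


def run_pipeline(config: PipelineConfig | None = None,
                 epochs: Epochs | None = None,
                 molecular: pd.DataFrame | None = None) -> ResultsBundle:
    """Execute the full analysis.

    With no ``epochs`` argument the cohort is simulated from
    ``config.simulation`` (subject-by-subject); otherwise the provided
    trial-level epochs (and optional molecular table) are analyzed.
    """
    config = config or PipelineConfig()
    config.simulation.seed = config.seed
    sim = CohortSimulator(config.simulation, config.layout)
    truth = None
    comp_frames, rej_frames = [], []
    extractor = ComponentExtractor(config.layout)

    if epochs is None:
        truth = sim.truth()
        log.info("simulated %d subjects", len(truth))
        for i in range(len(truth)):
            one = truth.iloc[[i]]
            ep = sim.epochs(one)
            avgs = preprocess_epochs(ep, config.layout, config.preprocess)
            comp_frames.append(extractor.transform(avgs))
            if avgs.rejection_log is not None:
                rej_frames.append(_summarize_log(avgs.rejection_log))
        molecular = sim.molecular(truth)
    else:
        avgs = preprocess_epochs(epochs, config.layout, config.preprocess)
        comp_frames.append(extractor.transform(avgs))
        if avgs.rejection_log is not None:
            rej_frames.append(_summarize_log(avgs.rejection_log))

    components = pd.concat(comp_frames, ignore_index=True).sort_values(
        ["subject", "window", "hemisphere", "condition"],
        ignore_index=True)
    rejection = (pd.concat(rej_frames, ignore_index=True)
                 if rej_frames else pd.DataFrame())

    scorer = LateralityScorer(config.epsilon_uV, config.z_reference)
    lat = scorer.transform(components)
    sens_tests = sensitivity_t_tests(components)
    summary = cohort_summary(lat) if lat.group.nunique() >= 2 \
        and lat.groupby("group").size().min() >= 3 else None

    correlations = None
    if molecular is not None and len(molecular):
        mol_z = zscore_within_batch(molecular)
        phen = lat.rename(columns={"LI_uV": "LI", "S_R_uV": "S_R",
                                   "S_L_uV": "S_L"})
        correlations = correlate_grid(mol_z, phen, config.plan,
                                      method=config.adjust_method)

    anova = _n2_anova(components)
    chi = _demographic_chi_square(lat)

    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "version": __version__}
    return ResultsBundle(truth, rejection, components, lat, sens_tests,
                         correlations, anova, chi, summary, manifest)


def _summarize_log(log_frame: pd.DataFrame) -> pd.DataFrame:
    out = (log_frame.groupby(["subject", "condition"], sort=True)
           .agg(n_total=("retained", "size"),
                n_retained=("retained", "sum")).reset_index())
    out["retained_fraction"] = out.n_retained / out.n_total
    return out


def _n2_anova(components: pd.DataFrame) -> pd.DataFrame:
    """Group x scroll-direction x hemisphere ANOVA on N2 mean amplitude."""
    n2 = components[components["window"] == "N2"]
    if n2.empty or n2.group.nunique() < 2:
        return pd.DataFrame()
    res = mixed_anova(n2.rename(columns={"mean_amplitude_uV": "amp"}),
                      dv="amp", subject="subject", between="group",
                      within=["condition", "hemisphere"])
    return anova_table(res)


def _demographic_chi_square(lat: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if "handedness" in lat.columns and lat.group.nunique() == 2:
        groups = sorted(lat.group.unique())
        tab = np.array([
            [(lat.group.eq(g) & lat.handedness.eq("L")).sum(),
             (lat.group.eq(g) & lat.handedness.eq("R")).sum()]
            for g in groups])
        if tab.sum(axis=0).all() and tab.sum(axis=1).all():
            res = chi_square_2x2(tab)
            rows.append({"comparison": "handedness x group",
                         "chi2": res.statistic, "df": res.df, "p": res.p,
                         "n": int(tab.sum())})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- reporting
def _manifest_lines(manifest: dict) -> list[str]:
    return [f"{k}: {v}" for k, v in manifest.items()]


def _write_table(frame: pd.DataFrame, path: str, manifest: dict) -> None:
    buf = io.StringIO()
    for line in _manifest_lines(manifest):
        buf.write(f"# {line}\n")
    frame.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_bundle(bundle: ResultsBundle, out_dir: str) -> dict[str, str]:
    """Write all result tables; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    tables = {
        "truth": bundle.truth, "rejection_log": bundle.rejection_summary,
        "component_measures": bundle.components,
        "laterality": bundle.laterality,
        "sensitivity_tests": bundle.sensitivity_tests,
        "correlations": bundle.correlations, "anova": bundle.anova,
        "chi_square": bundle.chi_square,
    }
    for name, frame in tables.items():
        if frame is None or (hasattr(frame, "empty") and frame.empty):
            continue
        path = os.path.join(out_dir, f"{name}.csv")
        _write_table(frame, path, bundle.manifest)
        paths[name] = path
    report = write_report(bundle)
    path = os.path.join(out_dir, "report.txt")
    with open(path, "w") as fh:
        fh.write(report)
    paths["report"] = path
    return paths


def write_report(bundle: ResultsBundle) -> str:
    """Human-readable run summary."""
    lines = ["motionlat run report",
             "====================",
             f"seed: {bundle.manifest['seed']}  "
             f"config: {bundle.manifest['config_hash']}  "
             f"version: {bundle.manifest['version']}", ""]
    lat = bundle.laterality
    for group, sub in lat.groupby("group", sort=True):
        lines.append(f"group {group}: n={len(sub)}  "
                     f"mean LI={sub.LI_uV.mean():+.3f} uV")
    if len(bundle.rejection_summary):
        frac = bundle.rejection_summary.retained_fraction.mean()
        lines.append(f"mean trial retention: {100 * frac:.1f}%")
    if bundle.summary is not None:
        lines.append("")
        lines.append("specialization (% of group):")
        pct = bundle.summary.class_percentages
        for _, r in pct[pct.handedness == "all"].iterrows():
            lines.append(f"  {r.group:3s} {r['class']:15s} {r.percent:5.1f}%")
        lines.append("inverse interhemispheric sensitivity:")
        for _, r in bundle.summary.interhemispheric.iterrows():
            lines.append(f"  {r.group:3s} r(S_R, S_L) = {r.r:+.3f} "
                         f"(p = {r.p:.4f}, n = {int(r.n)})")
        if bundle.summary.group_comparison:
            c = bundle.summary.group_comparison
            lines.append(f"LI {c['groups']}: t({c['df']}) = {c['t']:.3f}, "
                         f"p = {c['p']:.4f}")
    if bundle.correlations is not None and len(bundle.correlations):
        lines.append("")
        lines.append("molecular correlations (adjusted within phenotype):")
        for _, r in bundle.correlations.iterrows():
            lines.append(f"  {r.feature:12s} x {r.phenotype:4s} "
                         f"r = {r.r:+.3f}  p = {r.p:.4f}  "
                         f"p_adj = {r.p_adjusted:.4f}  ({r['tail']})")
    if len(bundle.anova):
        lines.append("")
        lines.append("N2 mixed ANOVA:")
        for _, r in bundle.anova.iterrows():
            lines.append(f"  {r.effect:35s} F({r.df_num},{r.df_den}) = "
                         f"{r.F:8.3f}  p = {r.p:.4f}")
    if len(bundle.chi_square):
        lines.append("")
        for _, r in bundle.chi_square.iterrows():
            lines.append(f"chi2 {r.comparison}: chi2(1,{r.n}) = "
                         f"{r.chi2:.3f}, p = {r.p:.3f}")
    return "\n".join(lines) + "\n"
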