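"""Assemble the per-PAT analyses into study-level tables and plots.

The full pipeline: clean the trial records, summarise the ratio
distributions, quantify intra-rater (test-retest) and inter-rater
reproducibility per PAT with banded kappas and condition-ICCs, and fit
the ZINB condition-effect model — but only for PATs whose ratios actually
vary.  A tracker that counts essentially perfectly everywhere (all ratios
hugging 1) offers nothing to reproduce, so such PATs are excluded from the
reproducibility quantification with a logged note; the default rule
excludes a PAT when at least 95 % of its ratios lie in [0.9, 1.1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, condition_effects, icc as icc_mod
from .preprocess import PATS, RatioDataset, clean_dataset

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable policies of the analysis pipeline."""

    chance_marginals: str = "pair"        # "pair" | "pooled"
    round_combos: str = "all"             # "all" | "cross"
    variation_band: tuple[float, float] = (0.9, 1.1)
    variation_frac: float = 0.95          # exclude PAT if >= this inside band
    true_steps_exposure: float = 20.0
    inflation: str = "condition"          # ZINB inflation component
    fit_condition_effects: bool = True


@dataclass
class StudyReport:
    """All pipeline outputs with suppression bookkeeping."""

    per_participant_intra: pd.DataFrame
    per_pat_inter: pd.DataFrame
    ratio_summary: pd.DataFrame
    condition_effects: dict[str, dict] = field(default_factory=dict)
    cleaning_log: dict = field(default_factory=dict)
    excluded_pats: dict[str, str] = field(default_factory=dict)
    inter_breakdowns: dict[str, pd.DataFrame] = field(default_factory=dict)


def limited_variation(data: RatioDataset, pat: str,
                      band: tuple[float, float] = (0.9, 1.1),
                      frac: float = 0.95) -> bool:
    """True when a PAT's ratios are too uniform for reproducibility analysis."""
    r = data.ratios(pat=pat)["ratio"]
    if r.empty:
        return True
    inside = ((r >= band[0]) & (r <= band[1])).mean()
    return bool(inside >= frac)


def summarize_ratios(data: RatioDataset) -> pd.DataFrame:
    """Per PAT x condition ratio distribution summary (pooled over rounds)."""
    g = data.table.groupby(["pat", "condition"])["ratio"]
    out = g.agg(n="count", mean="mean", sd="std", min="min", max="max",
                frac_zero=lambda s: float((s == 0).mean()))
    return out.reset_index()


def run_analysis(records: pd.DataFrame,
                 config: AnalysisConfig | None = None) -> StudyReport:
    """Execute the full analysis pipeline on a trial table."""
    config = config or AnalysisConfig()
    if records is None or len(records) == 0:
        raise ValueError("no trial records supplied")
    data = clean_dataset(records)
    if data.table.empty:
        raise ValueError("no records survive cleaning")

    excluded: dict[str, str] = {}
    analyzed: list[str] = []
    for pat in PATS:
        if data.ratios(pat=pat).empty:
            excluded[pat] = "no data"
            continue
        if limited_variation(data, pat, config.variation_band,
                             config.variation_frac):
            lo, hi = config.variation_band
            excluded[pat] = (
                f">= {config.variation_frac:.0%} of ratios within "
                f"[{lo}, {hi}]: too little variation to quantify reproducibility"
            )
            logger.info("PAT %s excluded: %s", pat, excluded[pat])
        else:
            analyzed.append(pat)

    intra_rows = []
    for pat in analyzed:
        for part in data.participants(pat=pat):
            k = agreement.intra_hcp_kappa(
                data, part, pat, chance_marginals=config.chance_marginals)
            i = icc_mod.intra_hcp_icc(data, part, pat)
            intra_rows.append({
                "participant_id": part, "pat": pat,
                "kappa": k.kappa, "kappa_label": k.label,
                "kappa_suppressed": k.suppressed, "kappa_reason": k.reason,
                "n_pairs": k.n_pairs,
                "icc": i.icc, "icc_suppressed": i.suppressed,
                "icc_reason": i.reason,
                "sigma_condition": i.sigma_condition,
            })
    per_participant = pd.DataFrame(intra_rows)

    inter_rows = []
    breakdowns: dict[str, pd.DataFrame] = {}
    for pat in analyzed:
        kres, kbd = agreement.inter_hcp_kappa(
            data, pat, chance_marginals=config.chance_marginals,
            round_combos=config.round_combos)
        ires, ibd = icc_mod.inter_hcp_icc(data, pat,
                                          round_combos=config.round_combos)
        if not per_participant.empty:
            sub = per_participant[per_participant["pat"] == pat]
            mean_intra_kappa = sub.loc[~sub["kappa_suppressed"], "kappa"].mean()
            mean_intra_icc = sub.loc[~sub["icc_suppressed"], "icc"].mean()
        else:
            mean_intra_kappa = mean_intra_icc = np.nan
        inter_rows.append({
            "pat": pat,
            "kappa": kres.kappa, "kappa_label": kres.label,
            "kappa_suppressed": kres.suppressed, "kappa_reason": kres.reason,
            "icc": ires.icc, "icc_suppressed": ires.suppressed,
            "icc_reason": ires.reason,
            "mean_intra_kappa": (None if pd.isna(mean_intra_kappa)
                                 else float(mean_intra_kappa)),
            "mean_intra_icc": (None if pd.isna(mean_intra_icc)
                               else float(mean_intra_icc)),
        })
        breakdowns[pat] = kbd
    per_pat = pd.DataFrame(inter_rows)

    effects: dict[str, dict] = {}
    if config.fit_condition_effects:
        for pat in analyzed:
            trials = data.ratios(pat=pat)
            try:
                fit = condition_effects.fit_zinb(
                    trials, inflation=config.inflation,
                    true_steps_exposure=config.true_steps_exposure)
                mm = condition_effects.marginal_means(fit)
                contrasts, global_test = condition_effects.contrast_tests(fit)
                effects[pat] = {
                    "fit": fit, "marginal_means": mm,
                    "contrasts": contrasts, "global_test": global_test,
                }
            except condition_effects.FitError as exc:
                logger.warning("condition-effect fit failed for %s: %s",
                               pat, exc)
                effects[pat] = {"error": str(exc)}

    return StudyReport(
        per_participant_intra=per_participant,
        per_pat_inter=per_pat,
        ratio_summary=summarize_ratios(data),
        condition_effects=effects,
        cleaning_log=data.report.as_dict(),
        excluded_pats=excluded,
        inter_breakdowns=breakdowns,
    )


# ---------------------------------------------------------------------------
# plots


def bubble_plot_data(data: RatioDataset, pat: str,
                     round_to: float = 0.05) -> pd.DataFrame:
    """Bubble positions/sizes for the ratio-distribution plot of one PAT.

    Ratios are binned to a grid so repeated observations stack into one
    bubble whose *area* is proportional to the observation count.
    """
    t = data.ratios(pat=pat).copy()
    t["ratio_bin"] = (t["ratio"] / round_to).round() * round_to
    counts = (t.groupby(["condition", "ratio_bin"]).size()
              .rename("n").reset_index())
    counts["area"] = counts["n"].astype(float)
    means = t.groupby("condition")["ratio"].mean().rename("mean_ratio")
    return counts.merge(means, on="condition")


def plot_ratio_distributions(data: RatioDataset, out_dir: str | Path,
                             dpi: int = 120) -> dict[str, Path]:
    """Write one bubble plot per PAT; returns the figure paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    order = [c for c in data.table["condition"].unique()]
    for pat in PATS:
        bubbles = bubble_plot_data(data, pat)
        if bubbles.empty:
            continue
        conditions = [c for c in order if c in set(bubbles["condition"])]
        xpos = {c: i for i, c in enumerate(conditions)}
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.scatter([xpos[c] for c in bubbles["condition"]],
                   bubbles["ratio_bin"],
                   s=30.0 * bubbles["area"], alpha=0.5, edgecolor="k")
        mean_by_cond = (bubbles.drop_duplicates("condition")
                        .set_index("condition")["mean_ratio"])
        ax.plot([xpos[c] for c in conditions],
                [mean_by_cond[c] for c in conditions], "r-", lw=1.5,
                label="mean ratio")
        ax.set_xticks(range(len(conditions)), conditions, rotation=45)
        ax.set_ylabel("step count ratio")
        ax.set_title(f"{pat} sensor")
        ax.legend(loc="best")
        fig.tight_layout()
        path = out_dir / f"ratios_{pat}.png"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written[pat] = path
    return written


# ---------------------------------------------------------------------------
# serialization


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write all report tables as CSV/JSON under one directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_participant_intra.to_csv(out / "intra_rater.csv", index=False)
    report.per_pat_inter.to_csv(out / "inter_rater.csv", index=False)
    report.ratio_summary.to_csv(out / "ratio_summary.csv", index=False)
    for pat, eff in report.condition_effects.items():
        if "marginal_means" in eff:
            eff["marginal_means"].to_csv(
                out / f"marginal_means_{pat}.csv", index=False)
            eff["contrasts"].to_csv(out / f"contrasts_{pat}.csv", index=False)
    meta = {
        "cleaning_log": report.cleaning_log,
        "excluded_pats": report.excluded_pats,
        "global_tests": {
            pat: {k: v for k, v in eff["global_test"].items()
                  if k != "joint_tests"}
            for pat, eff in report.condition_effects.items()
            if "global_test" in eff
        },
    }
    (out / "report_meta.json").write_text(json.dumps(meta, indent=2))


def load_report(out_dir: str | Path) -> StudyReport:
    """Reload the CSV/JSON tables written by :func:`write_report`."""
    out = Path(out_dir)
    meta = json.loads((out / "report_meta.json").read_text())
    effects: dict[str, dict] = {}
    for mm_path in sorted(out.glob("marginal_means_*.csv")):
        pat = mm_path.stem.replace("marginal_means_", "")
        effects[pat] = {
            "marginal_means": pd.read_csv(mm_path),
            "contrasts": pd.read_csv(out / f"contrasts_{pat}.csv"),
            "global_test": meta["global_tests"].get(pat, {}),
        }
    return StudyReport(
        per_participant_intra=pd.read_csv(out / "intra_rater.csv"),
        per_pat_inter=pd.read_csv(out / "inter_rater.csv"),
        ratio_summary=pd.read_csv(out / "ratio_summary.csv"),
        condition_effects=effects,
        cleaning_log=meta["cleaning_log"],
        excluded_pats=meta["excluded_pats"],
    )
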