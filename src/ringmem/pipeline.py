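"""End-to-end orchestration: simulate a cohort, analyze every subject, run
the group statistics, and emit a reproducible report.

Per subject the pipeline fits the pairwise GLM per block and evaluates the
three principal contrasts (expression and interference in aLOC, opportunity
in the hippocampus), fits the trialwise GLM for RSA in the hippocampus and
scores the context- and relational-separation models, summarizes the memory
test (accuracy, foil errors), and extracts the metabolite changes. Group
statistics mirror the study's analysis set: signed-rank tests on the RSA
model fits, t tests on ROI contrasts and metabolite changes, partial
correlations along the GABA -> neural interference -> behavior chain, and
a permutation test for the block difference in the hippocampus-behavior
correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import glm, rsa, stats
from .design import DesignParams
from .rings import CONTEXTS
from .synth import (
    GroundTruth,
    SyntheticSubject,
    VoxelTimeSeries,
    simulate_subject,
)

logger = logging.getLogger("ringmem")

_SWAPPED_DEFAULT = (3, 6)


@dataclass
class PipelineConfig:
    n_subjects: int = 24
    master_seed: int = 0
    truth: GroundTruth = field(default_factory=GroundTruth)
    design: DesignParams = field(default_factory=DesignParams)
    distance_kind: str = "whitened_correlation"
    highpass_cutoff: float = 128.0
    shrinkage: object = "auto"
    n_perm: int = 10_000
    crlb_max: float = 50.0
    scan_accuracy_min: float = 0.80
    foil_fraction: float = 0.5
    randomize_rings: bool = True
    paired_permutation: bool = False
    data_dir: Optional[str] = None  # analyze an existing cohort directory

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("truth"), dict):
            d["truth"] = GroundTruth(**d["truth"])
        if isinstance(d.get("design"), dict):
            d["design"] = DesignParams(**d["design"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    subjects: pd.DataFrame
    group: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        self.group.to_csv(out / "group_stats.tsv", sep="\t", index=False)
        self.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(
                {
                    "provenance": self.provenance,
                    "group": self.group.to_dict(orient="records"),
                },
                indent=2,
                default=str,
            )
        )
        return out


# --------------------------------------------------------------------------
# Subject-level analysis

def _gaba_ratio(mrs, timepoint: str, crlb_max: float) -> float:
    kept = stats.mrs_quality_filter(mrs, crlb_max)
    vals = [m.ratio for m in kept if m.metabolite == "GABA" and m.timepoint == timepoint]
    return float(vals[0]) if vals else np.nan


def _glu_ratio(mrs, timepoint: str, crlb_max: float) -> float:
    kept = stats.mrs_quality_filter(mrs, crlb_max)
    vals = [m.ratio for m in kept if m.metabolite == "Glu" and m.timepoint == timepoint]
    return float(vals[0]) if vals else np.nan


def analyze_subject(subject: SyntheticSubject, config: PipelineConfig) -> dict:
    """All per-subject derived measures used by the group statistics."""
    tax = subject.tax
    specs = glm.contrast_specs(tax)
    row: Dict[str, float] = {"subject_id": subject.subject_id}

    trial_betas = []
    trial_info = []
    resid_covs = []
    for b in (1, 2):
        events = subject.events[b]
        n_vol = subject.bold[("hippocampus", b)].n_volumes
        pair_design = glm.build_design_matrix(
            events, "pairwise", config.design.tr, n_vol,
            highpass_cutoff=config.highpass_cutoff,
        )
        stacked = VoxelTimeSeries(
            data=np.vstack(
                [subject.bold[("hippocampus", b)].data, subject.bold[("aLOC", b)].data]
            ),
            tr=config.design.tr,
            roi_label="hippocampus+aLOC",
        )
        fit = glm.fit_glm(stacked, pair_design, compute_residuals=False)
        n_h = subject.bold[("hippocampus", b)].data.shape[0]
        hipp = np.arange(n_h)
        aloc = np.arange(n_h, stacked.data.shape[0])
        for name, spec in specs.items():
            roi = hipp if name == "opportunity" else aloc
            res = glm.compute_contrast(fit, spec, roi_mask=roi, block=b)
            row[f"{name}_b{b}"] = res.roi_mean
        # hippocampal opportunity contrast is also the behavior predictor
        row[f"opportunity_hipp_b{b}"] = row[f"opportunity_b{b}"]

        trial_design = glm.build_design_matrix(
            events, "trialwise", config.design.tr, n_vol,
            highpass_cutoff=config.highpass_cutoff,
        )
        tfit = glm.fit_glm(subject.bold[("hippocampus", b)], trial_design)
        trial_betas.append(tfit.betas[: len(events.trials)])
        info = events.to_frame()[["stim_first", "stim_second", "context", "oddball"]]
        trial_info.append(info)
        resid_covs.append(rsa.estimate_noise_covariance(tfit.residuals, config.shrinkage))

    noise_cov = 0.5 * (resid_covs[0] + resid_covs[1])
    rdm = rsa.trial_rdm(
        np.vstack(trial_betas),
        noise_cov,
        pd.concat(trial_info, ignore_index=True),
        distance_kind=config.distance_kind,
    )
    cond = rsa.condition_average_rdm(rdm)
    swapped = tuple(tax.swapped) or _SWAPPED_DEFAULT
    row["context_tau"] = rsa.rdm_model_fit(cond, rsa.context_separation_model())
    row["context_tau_excl_swapped"] = rsa.rdm_model_fit(
        cond, rsa.context_separation_model(exclude_stimuli=swapped)
    )
    row["relational_tau"] = rsa.rdm_model_fit(
        cond, rsa.relational_separation_model(swapped=swapped)
    )

    row["interference_change"] = row["interference_b2"] - row["interference_b1"]
    foil = stats.foil_statistics(subject.behavior.records)
    row["accuracy_pct"] = foil.accuracy_pct
    row["foil_error_pct"] = foil.foil_error_pct
    row["normalized_foil_error_pct"] = foil.normalized_foil_error_pct
    for context in CONTEXTS:
        row[f"learning_{context}"] = stats.learning_accuracy(
            subject.behavior.training_block_accuracy[context]
        )
    row["scan_accuracy_b1"], row["scan_accuracy_b2"] = subject.behavior.scan_accuracy
    row["gaba_t1"] = _gaba_ratio(subject.mrs, "t1", config.crlb_max)
    row["gaba_t2"] = _gaba_ratio(subject.mrs, "t2", config.crlb_max)
    row["gaba_t3"] = _gaba_ratio(subject.mrs, "t3", config.crlb_max)
    row["glu_t1"] = _glu_ratio(subject.mrs, "t1", config.crlb_max)
    row["glu_t3"] = _glu_ratio(subject.mrs, "t3", config.crlb_max)
    row["gaba_drop_meas"] = row["gaba_t1"] - row["gaba_t2"]
    row["glu_change_meas"] = row["glu_t3"] - row["glu_t1"]
    row["gaba_inestimable"] = subject.gaba_inestimable
    row["true_gaba_drop"] = subject.truth.gaba_drop
    row["true_trait"] = subject.truth.trait
    return row


def analyze_cohort(
    config: PipelineConfig, subjects: Optional[List[SyntheticSubject]] = None
) -> pd.DataFrame:
    """Simulate (subject by subject, unless given) and analyze a cohort."""
    rows = []
    if subjects is not None:
        for s in subjects:
            rows.append(analyze_subject(s, config))
        excl = stats.subject_exclusions(subjects, config.scan_accuracy_min)
    else:
        root = np.random.SeedSequence(config.master_seed)
        excl_rows = []
        for i, child in enumerate(root.spawn(config.n_subjects)):
            t0 = time.perf_counter()
            subject = simulate_subject(
                config.truth,
                child,
                subject_id=i,
                params=config.design,
                randomize_rings=config.randomize_rings,
                foil_fraction=config.foil_fraction,
            )
            rows.append(analyze_subject(subject, config))
            excl_rows.append(subject)
            logger.debug(
                "subject %d analyzed in %.2fs", i, time.perf_counter() - t0
            )
        excl = stats.subject_exclusions(excl_rows, config.scan_accuracy_min)
    df = pd.DataFrame(rows)
    return df.merge(excl, on="subject_id")


# --------------------------------------------------------------------------
# Group-level statistics

def group_statistics(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """The study's group-level analysis set on a per-subject table."""
    fmri = df[~df["fmri_excluded"]]
    mrs_ok = fmri[~fmri["mrs_excluded"]]
    out = []

    def add(name, statistic, p, tails, n, method):
        out.append(
            {
                "analysis": name,
                "statistic": float(statistic),
                "p_value": float(p),
                "tails": tails,
                "n": int(n),
                "method": method,
            }
        )

    # RSA model fits: two-sided signed-rank across participants
    for name in ("context_tau", "context_tau_excl_swapped", "relational_tau"):
        z, p = rsa.group_signrank(fmri[name].to_numpy())
        add(name, z, p, "two", len(fmri), "Wilcoxon signed-rank (Z)")

    # ROI contrasts
    opp = 0.5 * (fmri["opportunity_b1"] + fmri["opportunity_b2"])
    r = stats.one_sample_ttest(opp, tails="two")
    add("opportunity_both_blocks", r.statistic, r.p_value, r.tails, r.n, r.method)
    expr = 0.5 * (fmri["expression_b1"] + fmri["expression_b2"])
    r = stats.one_sample_ttest(expr, tails="one")
    add("expression_both_blocks", r.statistic, r.p_value, r.tails, r.n, r.method)
    r = stats.one_sample_ttest(fmri["interference_change"], tails="two")
    add("interference_b2_minus_b1", r.statistic, r.p_value, r.tails, r.n, r.method)
    r = stats.paired_ttest(fmri["opportunity_b1"], fmri["opportunity_b2"], tails="two")
    add("opportunity_b1_vs_b2", r.statistic, r.p_value, r.tails, r.n, r.method)

    # metabolites (one-tailed for the predicted GABA drop)
    m = mrs_ok.dropna(subset=["gaba_t1", "gaba_t2"])
    r = stats.paired_ttest(m["gaba_t1"], m["gaba_t2"], tails="one")
    add("gaba_t1_gt_t2", r.statistic, r.p_value, r.tails, r.n, r.method)
    m3 = mrs_ok.dropna(subset=["glu_t1", "glu_t3"])
    r = stats.paired_ttest(m3["glu_t3"], m3["glu_t1"], tails="two")
    add("glu_t3_vs_t1", r.statistic, r.p_value, r.tails, r.n, r.method)

    # GABA drop -> neural interference (Spearman, accounting for glutamate)
    sub = mrs_ok.dropna(subset=["gaba_drop_meas", "interference_change", "glu_change_meas"])
    if len(sub) > 4:
        pc = stats.partial_correlation(
            stats.PartialCorrInputs(
                yi=sub["gaba_drop_meas"].to_numpy(),
                yj=sub["interference_change"].to_numpy(),
                xi=sub["glu_change_meas"].to_numpy(),
                xj=sub["glu_change_meas"].to_numpy(),
            ),
            method="spearman",
        )
        add("gaba_drop_vs_interference", pc.r, pc.p, "two", len(sub), "partial Spearman")

    nuis_cols = ["learning_memory1", "learning_memory2", "gaba_drop_meas", "glu_change_meas"]
    if len(sub) > len(nuis_cols) + 3:  # enough residual degrees of freedom
        nuis = sub[nuis_cols].to_numpy()
        for outcome, name in (
            ("foil_error_pct", "interference_vs_foil_errors"),
            ("accuracy_pct", "interference_vs_accuracy"),
        ):
            pc = stats.partial_correlation(
                stats.PartialCorrInputs(
                    yi=sub["interference_change"].to_numpy(),
                    yj=sub[outcome].to_numpy(),
                    xi=nuis,
                    xj=nuis,
                ),
                method="spearman",
            )
            add(name, pc.r, pc.p, "two", len(sub), "partial Spearman")

    # hippocampus -> behavior per block (Pearson, accounting for learning)
    learn = fmri[["learning_memory1", "learning_memory2"]].to_numpy()
    hip_r = {}
    for b in (1, 2):
        pc = stats.partial_correlation(
            stats.PartialCorrInputs(
                yi=fmri[f"opportunity_hipp_b{b}"].to_numpy(),
                yj=fmri["foil_error_pct"].to_numpy(),
                xi=learn,
                xj=learn,
            ),
            method="pearson",
        )
        hip_r[b] = pc.r
        add(
            f"hippocampus_b{b}_vs_foil_errors", pc.r, pc.p, "two", len(fmri),
            "partial Pearson",
        )

    obs, p = stats.correlation_difference_permutation(
        fmri["opportunity_hipp_b1"].to_numpy(),
        fmri["opportunity_hipp_b2"].to_numpy(),
        fmri["foil_error_pct"].to_numpy(),
        n_perm=config.n_perm,
        seed=config.master_seed + 7919,
        paired=config.paired_permutation,
    )
    add(
        "hippocampus_block_correlation_difference", obs, p, "two", len(fmri),
        f"permutation ({config.n_perm} iterations)",
    )
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    t0 = time.perf_counter()
    logger.info("pipeline start: %d subjects, seed %d", config.n_subjects, config.master_seed)
    if config.data_dir is not None:
        from . import io as rio

        subjects = rio.read_cohort_dir(config.data_dir)
        df = analyze_cohort(config, subjects=subjects)
    else:
        df = analyze_cohort(config)
    logger.info("cohort analyzed in %.1fs", time.perf_counter() - t0)
    group = group_statistics(df, config)
    excl = df[["subject_id", "fmri_excluded", "mrs_excluded", "reason"]]
    provenance = {
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "config_hash": config.config_hash(),
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }
    return AnalysisReport(
        subjects=df.drop(columns=["reason"]),
        group=group,
        exclusions=excl,
        provenance=provenance,
    )
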