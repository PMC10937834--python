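"""End-to-end orchestration: preprocess → melatonin → rhythm → census →
differential expression → rotated PCA.

``run_pipeline`` executes the stages in order on either a synthetic cohort
(generated from a :class:`~rhythmix.synth.SimConfig`) or on files, writing
each stage's tables plus a JSON provenance record (inputs, parameters,
seed, package version — no wall-clock timestamps, so identical
config + seed reruns are byte-identical). A stage failure halts the run
with a stage-named error; earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .census import (acrophase_chisq, acrophase_histogram,
                     compare_distributions_ks, overlap_matrices,
                     rhythmic_counts_chisq)
from .cosinor import BootstrapSettings, fit_session
from .data import QC_COLUMNS
from .diffexpr import fit_de_batch, volcano_summary
from .io import write_gem, write_json, write_melatonin, write_meta, write_table
from .melatonin import align_times, compute_offsets, offset_session_anova
from .pca import pca, score_anova, score_rhythm, varimax_rotate
from .preprocess import (batch_adjust, participant_center, probe_filter,
                         quantile_normalize, sample_qc_filter)
from .synth import SimConfig, generate_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "melatonin", "rhythm", "census", "diffexpr", "pca")


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic-input mode)."""

    sim: SimConfig = field(default_factory=SimConfig)
    tau: float = 24.0
    rhythm_alpha: float = 0.05
    de_alpha: float = 0.01
    variant: str = "slopes"
    bootstrap_replicates: int = 200
    bootstrap_enabled: bool = False
    seed: int = 0
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        for name in ("rhythm_alpha", "de_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _provenance(out_dir: Path, stage: str, params: dict, outputs: list):
    write_json(
        {"stage": stage, "version": __version__, "parameters": params,
         "outputs": sorted(outputs)},
        out_dir / f"{stage}_provenance.json",
    )


def _ensure_dir(path: Path, force: bool):
    if path.exists() and any(path.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {path} is not empty; pass force=True to overwrite"
        )
    path.mkdir(parents=True, exist_ok=True)


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Run the configured stages on a synthetic cohort; returns result objects."""
    out = Path(out_dir)
    _ensure_dir(out, force)
    results: dict = {}
    stage = "generate"
    try:
        gem, meta, melatonin, truth = generate_cohort(config.sim)
        results.update(gem=gem, meta=meta, melatonin=melatonin, truth=truth)
        write_gem(gem, out / "gem_raw.tsv")
        write_meta(meta, out / "sample_meta.tsv")
        write_melatonin(melatonin, out / "melatonin.csv",
                        out / "melatonin_truth.csv")
        write_table(truth, out / "truth.tsv")
        _provenance(out, "generate", config.sim.to_dict(),
                    ["gem_raw.tsv", "sample_meta.tsv", "melatonin.csv", "truth.tsv"])

        if "preprocess" in config.stages:
            stage = "preprocess"
            qc = meta.set_index("sample_id")[QC_COLUMNS]
            retained, report = sample_qc_filter(gem, qc.reset_index())
            gem_f = gem.subset(samples=retained)
            meta_f = meta[meta["sample_id"].isin(retained)].reset_index(drop=True)
            gem_qn = quantile_normalize(gem_f)
            kept_probes = probe_filter(gem_qn)
            gem_qn = gem_qn.subset(transcripts=kept_probes)
            results.update(gem_qn=gem_qn, meta_f=meta_f, qc_report=report)
            write_gem(gem_qn, out / "gem_qn.tsv")
            write_json(report, out / "qc_report.json")
            _provenance(out, "preprocess", {"n_probes": len(kept_probes)},
                        ["gem_qn.tsv", "qc_report.json"])
        else:
            gem_qn, meta_f = gem, meta
            results.update(gem_qn=gem_qn, meta_f=meta_f)

        if "melatonin" in config.stages:
            stage = "melatonin"
            offsets = compute_offsets(melatonin)
            anova = offset_session_anova(offsets)
            results.update(offsets=offsets, offset_anova=anova)
            write_table(offsets, out / "melatonin_offsets.tsv")
            write_table(anova.anova_table, out / "offset_anova.tsv")
            write_table(anova.ls_means("session"), out / "offset_lsmeans.tsv")
            _provenance(out, "melatonin", {"baseline": "midday"},
                        ["melatonin_offsets.tsv", "offset_anova.tsv",
                         "offset_lsmeans.tsv"])
            aligned = align_times(meta_f, offsets)
        else:
            offsets = None
            aligned = None

        rhythm_results = {}
        per_participant = {}
        if "rhythm" in config.stages:
            stage = "rhythm"
            if aligned is None:
                offsets = compute_offsets(melatonin)
                aligned = align_times(meta_f, offsets)
            boot = (
                BootstrapSettings(config.bootstrap_replicates, seed=config.seed)
                if config.bootstrap_enabled else None
            )
            for sess, grp in aligned.groupby("session", sort=False):
                res, pp = fit_session(
                    gem_qn.values[grp["sample_id"]], grp, tau=config.tau,
                    variant=config.variant, alpha=config.rhythm_alpha,
                    bootstrap=boot,
                )
                rhythm_results[sess] = res
                per_participant[sess] = pp
                write_table(res.reset_index(), out / f"rhythm_{sess}.tsv")
            results.update(rhythm=rhythm_results, rhythm_per_participant=per_participant)
            _provenance(out, "rhythm",
                        {"variant": config.variant, "tau": config.tau,
                         "alpha": config.rhythm_alpha},
                        [f"rhythm_{s}.tsv" for s in rhythm_results])

        if "census" in config.stages and rhythm_results:
            stage = "census"
            flags = pd.DataFrame({
                s: r["rhythmic"] for s, r in rhythm_results.items()
            })
            census = overlap_matrices(flags)
            chi2, dof, p = rhythmic_counts_chisq(flags)
            amps = {s: r.loc[r["rhythmic"], "amp"] for s, r in rhythm_results.items()}
            r2s = {s: r.loc[r["rhythmic"], "r2c"] for s, r in rhythm_results.items()}
            n_rhy = {s: int(v.size) for s, v in amps.items()}
            ks_amp = (compare_distributions_ks(amps, "amp")
                      if min(n_rhy.values()) >= 2 else pd.DataFrame())
            ks_r2 = (compare_distributions_ks(r2s, "r2c")
                     if min(n_rhy.values()) >= 2 else pd.DataFrame())
            mean_off = (
                offsets[offsets["detectable"]]
                .groupby("session")["offset_hours"].mean()
                if offsets is not None else pd.Series(dtype=float)
            )
            hists = {}
            for s, r in rhythm_results.items():
                acro = r.loc[r["rhythmic"], "acrophase"]
                hists[s] = acrophase_histogram(
                    acro, tau=config.tau,
                    clock_offset=float(mean_off.get(s, 0.0)),
                )
            sessions = list(hists)
            chis = []
            for i in range(len(sessions)):
                for j in range(i + 1, len(sessions)):
                    try:
                        c2, dd, pp_ = acrophase_chisq(hists[sessions[i]],
                                                      hists[sessions[j]])
                    except ValueError:
                        c2, dd, pp_ = np.nan, 0, np.nan
                    chis.append({"session_a": sessions[i], "session_b": sessions[j],
                                 "chi2": c2, "df": dd, "p": pp_})
            results.update(census=census, census_chisq=(chi2, dof, p),
                           ks_amp=ks_amp, ks_r2=ks_r2, acro_hist=hists,
                           acro_chisq=pd.DataFrame(chis))
            write_table(census.jaccard, out / "overlap_jaccard.tsv", index=True)
            write_table(census.conditional, out / "overlap_conditional.tsv", index=True)
            write_json({"counts": census.counts.to_dict(),
                        "percentages": census.percentages.to_dict(),
                        "always_rhythmic": census.always_rhythmic,
                        "counts_chi2": {"chi2": chi2, "df": dof, "p": p}},
                       out / "census.json")
            if len(ks_amp):
                write_table(ks_amp, out / "ks_amplitude.tsv")
                write_table(ks_r2, out / "ks_r2.tsv")
            hist_df = pd.DataFrame(hists).T
            hist_df.columns = [f"h{h:02d}" for h in range(24)]
            write_table(hist_df, out / "acrophase_histograms.tsv", index=True)
            write_table(pd.DataFrame(chis), out / "acrophase_chisq.tsv")
            _provenance(out, "census", {}, ["census.json", "overlap_jaccard.tsv",
                                            "overlap_conditional.tsv",
                                            "acrophase_histograms.tsv",
                                            "acrophase_chisq.tsv"])

        if "diffexpr" in config.stages:
            stage = "diffexpr"
            de = fit_de_batch(gem_qn.values, meta_f, alpha=config.de_alpha)
            results["diffexpr"] = de
            write_table(de.anova.reset_index(), out / "de_anova.tsv")
            write_table(de.contrasts, out / "de_contrasts.tsv")
            write_table(de.calls, out / "de_calls.tsv")
            pair_summ = {}
            for (a, b) in {(x, y) for x, y in
                           zip(de.calls["session_a"], de.calls["session_b"])}:
                v = volcano_summary(de, (a, b))
                pair_summ[f"{a}|{b}"] = {k: v[k] for k in
                                         ("n_up", "n_down", "pct_significant")}
            write_json(pair_summ, out / "de_summary.json")
            _provenance(out, "diffexpr", {"alpha": config.de_alpha},
                        ["de_anova.tsv", "de_contrasts.tsv", "de_calls.tsv",
                         "de_summary.json"])

        if "pca" in config.stages:
            stage = "pca"
            gem_b = batch_adjust(
                gem_qn,
                meta_f.set_index("sample_id").loc[gem_qn.samples, "leg"].to_numpy(),
            )
            gem_c = participant_center(gem_b, meta_f)
            pres = pca(gem_c.values)
            k = min(4, pres.scores.shape[1])
            pres = varimax_rotate(pres, k=k)
            results["pca"] = pres
            sa = score_anova(pres.rotated_scores, meta_f)
            sr = None
            if aligned is not None:
                sr = score_rhythm(pres.rotated_scores, aligned, tau=config.tau)
                results["score_rhythm"] = sr
                write_table(sr["results"], out / "rpc_rhythm.tsv")
            results["score_anova"] = sa
            write_table(pres.rotated_scores, out / "rpc_scores.tsv", index=True)
            write_table(pres.rotated_loadings, out / "rpc_loadings.tsv", index=True)
            write_json({"eigenvalues": pres.eigenvalues[:10],
                        "pct_variance": pres.pct_variance[:10],
                        "rotated_pct_variance": pres.rotated_pct_variance},
                       out / "pca_variance.json")
            write_table(
                pd.concat([v.anova_table.assign(component=c) for c, v in sa.items()]),
                out / "rpc_anova.tsv",
            )
            _provenance(out, "pca", {"k": k},
                        ["rpc_scores.tsv", "rpc_loadings.tsv", "pca_variance.json",
                         "rpc_anova.tsv"])

        write_json({"config": config.to_dict(), "version": __version__},
                   out / "run_provenance.json")
    except Exception as err:  # preserve partial outputs, name the stage
        raise StageError(stage, err) from err
    return results
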