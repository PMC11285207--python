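"""End-to-end orchestration on synthetic cohorts.

Runs, for a CD-like and an ME/CFS-like cohort mimic sharing one peptide
library: count simulation -> normalization/scoring/QC -> per-sample
flagellin burden and cohort tests -> prevalence ratios and relative-position
profiles -> domain annotation -> class-similarity profiling (full-length and
N/C-domain scopes, bound and unbound sets) -> rank statistics.  Everything
is seeded; outputs are TSV tables, a JSON summary, and two plots.

Planted signal encodes the qualitative structure the analysis should
recover: both mimics share an N-terminal signature over stimulator and
silent flagellins; the CD-like mimic adds a C-terminal signature over
stimulator flagellins only, while the ME/CFS-like mimic adds a small
mixed-class C-terminal set and a pathogen-evader set at higher prevalence
than in the CD-like mimic.
"""

from __future__ import annotations

import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, enrich, seqcompare, stats_report, synthgen
from .errors import FlagseqError
from .librarydesign import TilingParams

logger = logging.getLogger("flagseq.pipeline")

COHORTS = ("cd_like", "mecfs_like")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None
    n_per_class: int = 20
    n_nonflagellin: int = 200
    tile_max_len: int = 64
    tile_overlap: int = 20
    n_cases: int = 40
    n_controls: int = 40
    total_reads_per_sample: int = 200_000
    gp_dispersion: float = 0.2
    enrichment_factor_range: tuple = (10.0, 50.0)
    alpha: float = 0.05
    min_input: int = 25
    cap: int = 1_250_000
    floor: int = 0
    min_enriched: int = 0
    min_bin_obs: int = 200
    n_refs_per_class: int = 5
    prevalence_threshold: float = 0.05
    # Signature prevalences (case, control).
    n_signature_prev: tuple = (0.7, 0.15)
    cd_c_signature_prev: tuple = (0.2, 0.0)
    me_c_signature_prev: tuple = (0.15, 0.0)
    evader_signature_prev_me: tuple = (0.2, 0.02)
    evader_signature_prev_cd: tuple = (0.08, 0.02)
    # Fraction of stimulator/silent flagellins held out of every signature
    # so that a genuinely unbound set exists.
    holdout_fraction: float = 0.25
    attach_prob_range: tuple = (0.02, 1.0)
    # Sizes (in flagellins) of the small discordant sets: the mixed-class
    # C-terminal set bound in the ME/CFS mimic and the pathogen-evader set.
    c_mixed_per_class: int = 8
    evader_subset: int = 4
    zero_signal: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        for key in ("enrichment_factor_range", "n_signature_prev",
                    "cd_c_signature_prev", "me_c_signature_prev",
                    "evader_signature_prev_me", "evader_signature_prev_cd",
                    "attach_prob_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _stage(name):
    logger.info("[%s] %s", time.strftime("%H:%M:%S"), name)


def build_signatures(annotations, seed, holdout_fraction=0.25,
                     attach_prob_range=(0.02, 1.0), c_mixed_per_class=8,
                     evader_subset=4):
    """Derive planted peptide sets from the library annotation table.

    Per-peptide attachment probabilities are drawn once here, so the two
    cohort mimics share per-peptide prevalence structure.  A random fraction
    of stimulator/silent flagellins is held out of all signatures (the
    future 'unbound' set).
    """
    rng = np.random.default_rng(seed)
    flg = annotations[annotations["is_flagellin"]]
    ss_parents = sorted(flg[flg["parent_class"].isin(
        ["stimulator", "silent"])]["parent_id"].unique())
    n_hold = int(round(holdout_fraction * len(ss_parents)))
    held_out = set(rng.choice(ss_parents, size=n_hold, replace=False)) \
        if n_hold else set()

    def parents_of(cls):
        parents = sorted(set(flg[flg["parent_class"] == cls]["parent_id"])
                         - held_out)
        return parents

    def peptide_set(parents, overlap_col):
        mask = (flg["parent_id"].isin(parents) & (flg[overlap_col] >= 0.5))
        return sorted(flg.index[mask])

    def subset(parents, k):
        if k >= len(parents):
            return list(parents)
        return sorted(rng.choice(parents, size=k, replace=False))

    stim, silent, evader = (parents_of(c) for c in
                            ("stimulator", "silent", "evader"))
    sets = {
        "n_shared": peptide_set(stim + silent, "n_overlap_frac"),
        "c_stimulator": peptide_set(stim, "c_overlap_frac"),
        "c_mixed": peptide_set(stim + silent, "c_overlap_frac"),
        "evader_n": peptide_set(subset(evader, evader_subset),
                                "n_overlap_frac"),
    }
    # One U-shaped attachment probability per peptide, shared by every
    # signature and both cohort mimics, giving a wide per-peptide prevalence
    # spectrum whose ranks are concordant across cohorts.
    all_peps = sorted(set().union(*sets.values()))
    lo, hi = attach_prob_range
    draws = rng.beta(0.3, 0.3, size=len(all_peps))
    global_attach = {p: float(lo + (hi - lo) * d)
                     for p, d in zip(all_peps, draws)}
    attach = {name: {p: global_attach[p] for p in sets[name]}
              for name in sets}
    return sets, attach, held_out


def _cohort_design(cfg, sets, attach, cohort, seed):
    if cfg.zero_signal:
        planted, case_prev, ctrl_prev = {}, {}, {}
    elif cohort == "cd_like":
        planted = {"n_shared": sets["n_shared"],
                   "c_stimulator": sets["c_stimulator"],
                   "evader_n": sets["evader_n"]}
        case_prev = {"n_shared": cfg.n_signature_prev[0],
                     "c_stimulator": cfg.cd_c_signature_prev[0],
                     "evader_n": cfg.evader_signature_prev_cd[0]}
        ctrl_prev = {"n_shared": cfg.n_signature_prev[1],
                     "c_stimulator": cfg.cd_c_signature_prev[1],
                     "evader_n": cfg.evader_signature_prev_cd[1]}
    else:
        planted = {"n_shared": sets["n_shared"],
                   "c_mixed": sets["c_mixed"],
                   "evader_n": sets["evader_n"]}
        case_prev = {"n_shared": cfg.n_signature_prev[0],
                     "c_mixed": cfg.me_c_signature_prev[0],
                     "evader_n": cfg.evader_signature_prev_me[0]}
        ctrl_prev = {"n_shared": cfg.n_signature_prev[1],
                     "c_mixed": cfg.me_c_signature_prev[1],
                     "evader_n": cfg.evader_signature_prev_me[1]}
    return synthgen.CohortDesign(
        n_cases=cfg.n_cases, n_controls=cfg.n_controls,
        planted_peptide_sets=planted,
        case_binding_prevalence=case_prev,
        control_binding_prevalence=ctrl_prev,
        peptide_binding_probs={k: attach.get(k, {}) for k in planted},
        enrichment_factor_range=cfg.enrichment_factor_range,
        seed=seed)


def _seropositivity_matrix(calls, peptide_ids, sample_ids):
    sero = calls.pivot_table(index="peptide_id", columns="sample_id",
                             values="seropositive", aggfunc="first",
                             fill_value=False)
    return sero.reindex(index=peptide_ids, columns=sample_ids,
                        fill_value=False).astype(bool)


def _bound_parents(prevalence, annotations, threshold, overlap_col=None):
    """Flagellin parents with at least one peptide above the prevalence
    threshold in cases; optionally restricted to peptides overlapping a
    domain."""
    prevalent = prevalence[prevalence["prevalence_case"] > threshold]
    annot = annotations.loc[annotations.index.intersection(prevalent.index)]
    annot = annot[annot["is_flagellin"]]
    if overlap_col is not None:
        annot = annot[annot[overlap_col] >= 0.5]
    return sorted(annot["parent_id"].unique())


def _report_from_comparison(comp):
    out = {
        "omnibus": {"method": comp.omnibus.method,
                    "statistic": comp.omnibus.statistic,
                    "p": comp.omnibus.p},
        "class_means": comp.class_means,
        "pairwise": comp.pairwise.to_dict(orient="records"),
        "n_queries": comp.n_queries,
    }
    return out


def run_pipeline(config=None, **overrides):
    """Run the full synthetic analysis; returns a report dict (and writes
    a run directory when ``config.outdir`` is set)."""
    if config is None:
        config = PipelineConfig(**overrides)
    cfg = config
    t0 = time.time()
    report = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(cfg).items()},
              "stages": {}}

    try:
        _stage("generate reference panel and library")
        template = synthgen.default_template()
        panel = synthgen.generate_reference_panel(
            template, n_per_class=cfg.n_per_class, seed=cfg.seed)
        panel_by_id = {f.id: f for f in panel}
        tiles, annotations = synthgen.generate_library(
            panel, n_nonflagellin=cfg.n_nonflagellin,
            tiling_params=TilingParams(cfg.tile_max_len, cfg.tile_overlap),
            seed=cfg.seed + 1)

        # Held-out reference set for classification (disjoint from the
        # library panel).
        ref_panel = synthgen.generate_reference_panel(
            template, n_per_class=cfg.n_refs_per_class, seed=cfg.seed + 2)
        readouts = synthgen.assign_tlr5_readouts(ref_panel, seed=cfg.seed + 3)
        references = []
        for flg in ref_panel:
            label = classify.classify_reference(
                readouts.loc[flg.id, "binding"],
                readouts.loc[flg.id, "activation"], 1.0, 1.0)
            references.append(classify.ReferenceFlagellin(
                id=f"ref_{flg.id}", sequence=flg.sequence, class_label=label,
                n_domain=flg.true_n_domain, c_domain=flg.true_c_domain,
                binding=float(readouts.loc[flg.id, "binding"]),
                activation=float(readouts.loc[flg.id, "activation"])))
        report["stages"]["reference_classes_recovered"] = all(
            ref.class_label == flg.true_class
            for ref, flg in zip(references, ref_panel))

        sets, attach, held_out = build_signatures(
            annotations, seed=cfg.seed + 4,
            holdout_fraction=cfg.holdout_fraction,
            attach_prob_range=cfg.attach_prob_range,
            c_mixed_per_class=cfg.c_mixed_per_class,
            evader_subset=cfg.evader_subset)

        _stage("simulate and score cohorts")
        cohort_results = {}
        for c_idx, cohort in enumerate(COHORTS):
            design = _cohort_design(cfg, sets, attach, cohort,
                                    seed=cfg.seed + 10 + c_idx)
            sim = synthgen.simulate_counts(
                tiles, design, total_reads_per_sample=cfg.total_reads_per_sample,
                gp_dispersion=cfg.gp_dispersion)
            calls, qc = enrich.score_matrix(
                sim.input_counts, sim.output_counts, alpha=cfg.alpha,
                min_input=cfg.min_input, cap=cfg.cap, floor=cfg.floor,
                min_enriched=cfg.min_enriched, min_bin_obs=cfg.min_bin_obs,
                seed=cfg.seed + 20 + c_idx)
            groups = sim.metadata["group"].to_dict()
            burdens = stats_report.flagellin_burden(
                calls, annotations["is_flagellin"].to_dict(), groups)
            case_ratios = [b.flagellin_ratio for b in burdens
                           if b.group == "case"]
            ctrl_ratios = [b.flagellin_ratio for b in burdens
                           if b.group == "control"]
            burden_test = stats_report.wilcoxon_rank_sum(case_ratios,
                                                         ctrl_ratios)
            sero = _seropositivity_matrix(calls, list(annotations.index),
                                          list(sim.metadata.index))
            prevalence = seqcompare.prevalence_ratio(
                sero, sim.metadata["group"])
            age_test, sex_test = stats_report.cohort_balance_check(sim.metadata)
            cohort_results[cohort] = {
                "sim": sim, "calls": calls, "qc": qc, "sero": sero,
                "prevalence": prevalence, "burdens": burdens,
            }
            report["stages"][cohort] = {
                "n_samples_retained": int(qc["retained"].sum()),
                "burden_wilcoxon_p": burden_test.p,
                "burden_case_mean_ratio": float(np.mean(case_ratios)),
                "burden_control_mean_ratio": float(np.mean(ctrl_ratios)),
                "cohort_balance_age_p": age_test.p,
                "cohort_balance_sex_p": sex_test.p,
            }

        _stage("cross-cohort concordance")
        flag_peps = annotations.index[annotations["is_flagellin"]]
        prev_cd = cohort_results["cd_like"]["prevalence"].loc[flag_peps]
        prev_me = cohort_results["mecfs_like"]["prevalence"].loc[flag_peps]
        keep = ((prev_cd["prevalence_case"] > cfg.prevalence_threshold)
                | (prev_me["prevalence_case"] > cfg.prevalence_threshold))
        if keep.sum() >= 3:
            rho_test = stats_report.spearman_rho(
                prev_cd.loc[keep, "prevalence_case"],
                prev_me.loc[keep, "prevalence_case"])
            report["stages"]["cross_cohort"] = {
                "n_peptides": int(keep.sum()),
                "spearman_rho": rho_test.statistic,
                "spearman_p": rho_test.p,
            }
        else:
            report["stages"]["cross_cohort"] = {"n_peptides": int(keep.sum())}

        _stage("relative positions and domain annotation")
        n_ref_seqs = [(r.id, r.domain_seq("n_domain")) for r in references
                      if r.class_label == "stimulator"]
        n_ref_seqs += [(r.id, r.domain_seq("n_domain")) for r in references
                       if r.class_label == "silent"][:1]
        c_ref_seqs = [(r.id, r.domain_seq("c_domain")) for r in references
                      if r.class_label == "stimulator"]

        relpos_frames = {}
        domain_annotations = {}
        for cohort in COHORTS:
            prevalence = cohort_results[cohort]["prevalence"]
            prevalent = prevalence[
                prevalence["prevalence_case"] > cfg.prevalence_threshold]
            pep_annot = annotations.loc[
                annotations.index.intersection(prevalent.index)]
            pep_annot = pep_annot[pep_annot["is_flagellin"]]
            relpos = pd.DataFrame({
                "peptide_id": pep_annot.index,
                "parent_id": pep_annot["parent_id"],
                "rel_start": [
                    seqcompare.relative_start(s, pl) for s, pl in
                    zip(pep_annot["start"], pep_annot["parent_length"])],
                "prevalence_case": prevalent.loc[pep_annot.index,
                                                 "prevalence_case"],
                "prevalence_control": prevalent.loc[pep_annot.index,
                                                    "prevalence_control"],
                "prevalence_ratio": prevalent.loc[pep_annot.index,
                                                  "prevalence_ratio"],
            }).reset_index(drop=True)
            relpos_frames[cohort] = relpos

            bound_ids = _bound_parents(prevalence, annotations,
                                       cfg.prevalence_threshold)
            annots = {}
            for pid in bound_ids:
                flg = panel_by_id[pid]
                annots[pid] = seqcompare.annotate_domains(
                    flg.sequence, n_ref_seqs, c_ref_seqs, protein_id=pid)
            domain_annotations[cohort] = annots

        _stage("class-similarity profiling")
        similarity = {}
        for cohort in COHORTS:
            prevalence = cohort_results[cohort]["prevalence"]
            annots = domain_annotations[cohort]
            scope_specs = {
                "full_length": _bound_parents(prevalence, annotations,
                                              cfg.prevalence_threshold),
                "n_domain": _bound_parents(prevalence, annotations,
                                           cfg.prevalence_threshold,
                                           "n_overlap_frac"),
                "c_domain": _bound_parents(prevalence, annotations,
                                           cfg.prevalence_threshold,
                                           "c_overlap_frac"),
            }
            similarity[cohort] = {}
            for scope, parents in scope_specs.items():
                profiles = []
                for pid in parents:
                    flg = panel_by_id[pid]
                    ann = annots.get(pid)
                    prof = classify.profile_similarity(
                        pid, flg.sequence, references, scope,
                        query_n_domain=ann.n_domain if ann else None,
                        query_c_domain=ann.c_domain if ann else None)
                    if prof is not None:
                        profiles.append(prof)
                entry = {"n_queries": len(profiles)}
                if len(profiles) >= 3:
                    paired = classify.compare_class_similarity(
                        profiles, paired=True, alpha=cfg.alpha)
                    unpaired = classify.compare_class_similarity(
                        profiles, paired=False, alpha=cfg.alpha)
                    entry["friedman"] = _report_from_comparison(paired)
                    entry["kruskal_dunn"] = _report_from_comparison(unpaired)
                    entry["_profiles"] = profiles
                similarity[cohort][scope] = entry

        # Unbound set: held-out flagellins plus any flagellin never above
        # the prevalence threshold in either cohort.
        bound_any = set()
        for cohort in COHORTS:
            bound_any |= set(_bound_parents(cohort_results[cohort]["prevalence"],
                                            annotations,
                                            cfg.prevalence_threshold))
        unbound_ids = [f.id for f in panel if f.id not in bound_any]
        unbound_profiles = [
            classify.profile_similarity(pid, panel_by_id[pid].sequence,
                                        references, "full_length")
            for pid in unbound_ids]
        report["stages"]["unbound"] = {"n_queries": len(unbound_profiles)}
        bound_full = similarity["cd_like"]["full_length"].get("_profiles", [])
        if len(unbound_profiles) >= 3 and len(bound_full) >= 3:
            contrast = classify.bound_vs_unbound_contrast(
                bound_full, unbound_profiles, paired=False, alpha=cfg.alpha)
            report["stages"]["unbound"]["kruskal_dunn"] = \
                _report_from_comparison(contrast["unbound"])

        for cohort in COHORTS:
            report["stages"][cohort]["similarity"] = {
                scope: {k: v for k, v in entry.items()
                        if not k.startswith("_")}
                for scope, entry in similarity[cohort].items()}

        report["elapsed_seconds"] = time.time() - t0

        if cfg.outdir:
            _write_outputs(cfg, report, cohort_results, relpos_frames,
                           domain_annotations, similarity, tiles, annotations)
        return report
    except FlagseqError:
        raise
    except Exception as exc:  # pragma: no cover - stage-named failure path
        raise FlagseqError(f"pipeline stage failed: {exc}") from exc


def _write_outputs(cfg, report, cohort_results, relpos_frames,
                   domain_annotations, similarity, tiles, annotations):
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(report["config"], fh, sort_keys=True)
    synthgen.write_library_fasta(tiles, annotations, outdir / "library.fasta")
    annotations.to_csv(outdir / "library_annotations.tsv", sep="\t")
    for cohort in COHORTS:
        cdir = outdir / cohort
        cdir.mkdir(exist_ok=True)
        res = cohort_results[cohort]
        res["calls"].to_csv(cdir / "calls.tsv", sep="\t", index=False)
        res["qc"].to_csv(cdir / "qc.tsv", sep="\t", index=False)
        res["prevalence"].to_csv(cdir / "prevalence.tsv", sep="\t",
                                 index_label="peptide_id")
        res["sim"].metadata.to_csv(cdir / "metadata.tsv", sep="\t")
        relpos_frames[cohort].to_csv(cdir / "relpos.tsv", sep="\t",
                                     index=False)
        rows = []
        for pid, ann in domain_annotations[cohort].items():
            rows.append({"protein_id": pid, "length": ann.protein_length,
                         "n_start": ann.n_domain[0] if ann.n_domain else "",
                         "n_end": ann.n_domain[1] if ann.n_domain else "",
                         "c_start": ann.c_domain[0] if ann.c_domain else "",
                         "c_end": ann.c_domain[1] if ann.c_domain else ""})
        pd.DataFrame(rows).to_csv(cdir / "domains.tsv", sep="\t", index=False)
        profile_frames = [
            classify.profiles_to_frame(entry["_profiles"])
            for entry in similarity[cohort].values() if "_profiles" in entry]
        if profile_frames:
            pd.concat(profile_frames, ignore_index=True).to_csv(
                cdir / "class_similarity.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    if cfg.make_plots:
        _make_plots(outdir, relpos_frames, similarity)


def _make_plots(outdir, relpos_frames, similarity):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(COHORTS), figsize=(10, 4), sharey=True)
    for ax, cohort in zip(np.atleast_1d(axes), COHORTS):
        relpos = relpos_frames[cohort]
        ax.hist(relpos["rel_start"], bins=np.linspace(0, 1, 21),
                color="steelblue")
        ax.set_title(cohort)
        ax.set_xlabel("relative start position")
    axes[0].set_ylabel("prevalent flagellin peptides")
    fig.tight_layout()
    fig.savefig(outdir / "relative_start_positions.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(COHORTS), figsize=(10, 4), sharey=True)
    for ax, cohort in zip(np.atleast_1d(axes), COHORTS):
        entry = similarity[cohort].get("c_domain", {})
        profiles = entry.get("_profiles", [])
        if profiles:
            data = [[p.class_mean(cls) for p in profiles]
                    for cls in classify.CLASSES]
            ax.boxplot(data, tick_labels=list(classify.CLASSES))
        ax.set_title(f"{cohort}: C-domain identity")
        ax.set_ylabel("identity %")
    fig.tight_layout()
    fig.savefig(outdir / "c_domain_identity.png", dpi=120)
    plt.close(fig)
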