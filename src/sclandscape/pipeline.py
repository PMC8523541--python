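"""End-to-end orchestration with a single config and a reproducible report.

``run_pipeline`` executes the stages in dependency order — io ->
composition/DEG (independent) -> velocity -> metacell -> deconvolution ->
interactions — on an input manifest, writing per-stage TSV/JSON outputs and a
run report.  A failure in one branch does not abort independent branches;
the report records status, seeds, parameters and wall-clock per stage, which
is sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import deconvolution as dec
from . import diffexpr as de
from . import interactions as ia
from . import metacell as mc
from . import velocity as vel
from .io import read_manifest, patient_dominance_warnings
from .preprocess import lognormalize, select_hvg
from .simulate import child_seed


@dataclass
class RunConfig:
    """All stage parameters; defaults are the canonical analysis settings."""

    manifest: str = ""
    out_dir: str = "run_out"
    seed: int = 0
    # stage toggles
    stages: list = field(default_factory=lambda: [
        "composition", "deg", "velocity", "metacell", "deconvolution", "interactions",
    ])
    # composition
    alpha_family: float = 0.01
    residual_threshold: float = 3.5
    test_group: str = "MT"
    # DEG
    q_max: float = 0.05
    lfc_min: float = 0.25
    min_pct: float = 0.1
    deg_subsets: list = field(default_factory=list)  # empty -> all clusters
    # shared preprocessing
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    # velocity
    velocity_q: float = 0.05
    smoothing_k: int = 30
    kernel_k: int = 150
    sigma: float = 0.05
    # metacell
    k_graph: int = 100
    min_mc_size: int = 20
    anchors: list = field(default_factory=lambda: list(mc.DEFAULT_ANCHORS))
    targets: list = field(default_factory=lambda: list(mc.DEFAULT_TARGETS))
    # deconvolution
    bulk_tsv: str = ""
    response_tsv: str = ""
    designated_subset: str = "C2"
    signature_n_hvg: int = 7431
    # interactions
    pairs_tsv: str = ""
    n_perm: int = 1000
    interaction_senders: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage, status, seconds, outputs=None, warnings_=None, error=None):
        self.stages[stage] = {
            "status": status,
            "wall_clock_s": round(seconds, 3),
            "outputs": outputs or {},
            "warnings": warnings_ or [],
            "error": error,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=2))


def _log_line(log_path, stage, seed, status, params=None):
    entry = {"stage": stage, "seed": seed, "status": status, "params": params or {}}
    with open(log_path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    report = RunReport(config=asdict(config))
    config.to_yaml(out / "config_used.yaml")

    t0 = time.perf_counter()
    ac = read_manifest(config.manifest)
    norm = lognormalize(ac, config.scale_factor)
    hvg = select_hvg(norm, min(config.n_hvg, len(norm.gene_ids)))
    report.record("io", "ok", time.perf_counter() - t0,
                  outputs={"n_genes": ac.n_genes, "n_cells": ac.n_cells,
                           "n_hvg": len(hvg.gene_ids)},
                  warnings_=patient_dominance_warnings(ac.cell_meta))
    _log_line(log_path, "io", config.seed, "ok", {"manifest": config.manifest})

    clusters = ac.cell_meta["cluster"].to_numpy()
    groups = ac.cell_meta["group"].to_numpy()

    def _stage(name, fn):
        if name not in config.stages:
            return
        t = time.perf_counter()
        try:
            outputs = fn()
            report.record(name, "ok", time.perf_counter() - t, outputs=outputs)
            _log_line(log_path, name, config.seed, "ok")
        except Exception as exc:  # independent branches keep running
            status = "skipped" if str(exc).startswith("skipped") else "failed"
            report.record(name, status, time.perf_counter() - t, error=str(exc))
            _log_line(log_path, name, config.seed, f"{status}: {exc}")

    def _composition():
        res = comp.analyze_composition(
            ac.cell_meta, alpha_family=config.alpha_family,
            threshold=config.residual_threshold, test_group=config.test_group,
        )
        res.r.to_csv(out / "composition_residuals.tsv", sep="\t")
        geom = comp.mosaic_export(res.table, res, threshold=config.residual_threshold)
        geom.to_csv(out / "mosaic_geometry.tsv", sep="\t", index=False)
        comp.mosaic_svg(geom, out / "mosaic.svg")
        summary = {
            "chi2": res.chi2, "dof": res.dof, "p_gof": res.p_gof,
            "alpha_adjusted": res.alpha_adjusted,
            "calls": res.calls.to_dict(),
        }
        (out / "composition_summary.json").write_text(json.dumps(summary, indent=2))
        return {"p_gof": res.p_gof, "calls": res.calls.value_counts().to_dict()}

    def _deg():
        subsets = config.deg_subsets or sorted(set(clusters), key=str)
        frames = []
        for subset in subsets:
            frames.append(de.subset_degs(
                norm, ac.cell_meta, subset,
                q_max=config.q_max, lfc_min=config.lfc_min, min_pct=config.min_pct,
            ))
            frames.append(de.group_degs(
                norm, ac.cell_meta, subset,
                q_max=config.q_max, lfc_min=config.lfc_min, min_pct=config.min_pct,
            ))
        degs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        degs.to_csv(out / "degs.tsv", sep="\t", index=False)
        return {"n_deg_records": int(len(degs))}

    def _velocity():
        if "spliced" not in ac.layers or "unspliced" not in ac.layers:
            raise RuntimeError("skipped: no spliced/unspliced layers in manifest")
        results = {}
        for grp in sorted(set(groups)):  # groups processed separately
            mask = groups == grp
            idx = np.flatnonzero(mask)
            s = ac.layers["spliced"][:, idx]
            u = ac.layers["unspliced"][:, idx]
            fit = vel.fit_gamma(s, u, gene_ids=ac.gene_ids, q=config.velocity_q)
            field_ = vel.compute_velocity(
                fit, s, u, gene_ids=ac.gene_ids,
                cell_ids=[ac.cell_ids[i] for i in idx],
                smoothing_k=config.smoothing_k,
            )
            keep = [i for i, g in enumerate(ac.gene_ids) if g in fit.gamma.index]
            model = vel.transition_kernel(
                field_, s.toarray()[keep], k=config.kernel_k, sigma=config.sigma,
            )
            model = vel.subset_transitions(model, clusters[idx])
            model.M.to_csv(out / f"transitions_{grp}.tsv", sep="\t")
            if ac.embedding is not None:
                vel.embed_arrows(model, ac.embedding[idx]).to_csv(
                    out / f"arrows_{grp}.tsv", sep="\t"
                )
            results[grp] = model.persistence.round(4).to_dict()
        (out / "velocity_params.json").write_text(json.dumps({
            "q": config.velocity_q, "smoothing_k": config.smoothing_k,
            "kernel_k": config.kernel_k, "sigma": config.sigma,
            "persistence": results,
        }, indent=2))
        return {"persistence": results}

    def _metacell():
        hvg_idx = [norm.gene_ids.index(g) for g in hvg.gene_ids]
        frames = []
        for grp in sorted(set(groups)):  # groups pooled separately
            mask = groups == grp
            expr = norm.values[hvg_idx][:, np.flatnonzero(mask)].toarray().T
            part = mc.partition_metacells(
                expr, k_graph=config.k_graph, min_size=config.min_mc_size,
                seed=child_seed(config.seed, f"metacell:{grp}"),
            )
            from .io import AnnotatedCounts
            sub = AnnotatedCounts(
                ac.counts[:, np.flatnonzero(mask)], ac.gene_ids,
                [ac.cell_ids[i] for i in np.flatnonzero(mask)],
                ac.cell_meta.loc[mask],
            )
            frames.append((grp, mc.metacell_profiles(sub, part)))
        profiles = dict(frames)
        present = [g for g in set(config.anchors) | set(config.targets)
                   if g in norm.gene_ids]
        if len(present) < 2 or not any(a in present for a in config.anchors):
            return {"note": "anchor/target genes absent from data; correlation skipped",
                    "n_metacells": {g: p.profiles.shape[0] for g, p in profiles.items()}}
        anchors = [a for a in config.anchors if a in present]
        targets = [t for t in config.targets if t in present]
        grps = sorted(profiles)
        cmp_df = mc.compare_networks(
            profiles[grps[0]], profiles[grps[1]], anchors, targets,
            group_names=(grps[0], grps[1]),
        ) if len(grps) == 2 else pd.DataFrame()
        cmp_df.to_csv(out / "correlation_comparison.tsv", sep="\t", index=False)
        return {"n_pairs": int(len(cmp_df)),
                "n_metacells": {g: p.profiles.shape[0] for g, p in profiles.items()}}

    def _deconvolution():
        if not config.bulk_tsv:
            raise RuntimeError("skipped: no bulk TSV configured")
        sig_hvg = select_hvg(norm, min(config.signature_n_hvg, len(norm.gene_ids)))
        sig = dec.build_signature(norm, clusters, gene_set=sig_hvg.gene_ids)
        bulk = pd.read_csv(config.bulk_tsv, sep="\t", index_col=0)
        est = dec.estimate_fractions(bulk, sig)
        est.f.to_csv(out / "fractions.tsv", sep="\t")
        outputs = {"n_samples": int(est.f.shape[0])}
        if config.response_tsv:
            resp = pd.read_csv(config.response_tsv, sep="\t", index_col=0).iloc[:, 0]
            assess = dec.assess_response(est.f[config.designated_subset], resp)
            assess.waterfall.to_csv(out / "waterfall.tsv", sep="\t")
            outputs.update(
                auroc=assess.auroc, p_one_tailed=assess.p_one_tailed, u_stat=assess.u_stat
            )
            (out / "response_assessment.json").write_text(json.dumps(
                {k: outputs[k] for k in ("auroc", "p_one_tailed", "u_stat")}, indent=2))
        return outputs

    def _interactions():
        pairs = ia.load_pairs(config.pairs_tsv or None)
        pairs = [p for p in pairs
                 if p.ligand in norm.gene_ids and p.receptor in norm.gene_ids]
        if not pairs:
            return {"note": "no pair genes present in data"}
        subs = sorted(set(clusters), key=str)
        senders = config.interaction_senders or subs
        subset_pairs = [(a, b) for a in senders for b in subs if a != b]
        frames = []
        for grp in sorted(set(groups)):  # groups scored separately
            mask = groups == grp
            sub_norm = norm.subset_cells(mask)
            frames.append(ia.score_interactions(
                sub_norm, clusters[mask], pairs, subset_pairs,
                n_perm=config.n_perm,
                seed=child_seed(config.seed, f"interactions:{grp}"), group=grp,
            ))
        records = pd.concat(frames, ignore_index=True)
        records.to_csv(out / "interactions.tsv", sep="\t", index=False)
        ia.dotplot_export(records).to_csv(out / "dotplot.tsv", sep="\t", index=False)
        return {"n_records": int(len(records)),
                "n_expressed": int(records["expressed"].sum())}

    _stage("composition", _composition)
    _stage("deg", _deg)
    _stage("velocity", _velocity)
    _stage("metacell", _metacell)
    _stage("deconvolution", _deconvolution)
    _stage("interactions", _interactions)

    report.save(out / "run_report.json")
    return report
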