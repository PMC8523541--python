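"""Assemble complete synthetic study datasets from a scenario description.

A scenario bundles every planted structure the analysis stages look for —
composition shifts, subset markers, group-contrasted interaction axes,
WT-only co-regulation, splicing kinetics with a group-dependent transiting
fraction, and a pseudo-bulk responder cohort — and
:func:`simulate_dataset` writes the whole thing to disk (MTX trio, layer
files, bulk/response TSVs, a YAML manifest, and a ground-truth JSON that
records what was planted for recovery tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import simulate as sim
from .deconvolution import build_signature
from .io import AnnotatedCounts, write_manifest, write_mtx_trio
from .preprocess import lognormalize
import scipy.io


def default_scenario() -> dict:
    """A compact two-group study with all planted structures.

    Ten subsets: C2 plays the tissue-resident-memory-like role (depleted in
    MT, persistence eroded in MT, WT-only RBPJ co-regulation), C9 the
    follicular-helper-like role (depleted in MT, CXCL13 sender), C8 the
    B-cell role (depleted in MT, CXCR5 receiver), C1 augmented in MT.
    """
    return {
        "n_subsets": 10,
        "group_totals": {"WT": 2000, "MT": 2000},
        "mt_folds": {"C2": 0.4, "C9": 0.4, "C8": 0.4, "C1": 2.5},
        "n_genes": 400,
        "markers_per_subset": 4,
        "marker_fold": 6.0,
        "named_genes": {
            # gene -> (subset, fold, group or None)
            "CXCL13": ["C9", 8.0, None],
            "CXCR5": ["C8", 8.0, None],
            "ITGAE": ["C2", 6.0, None],
            "RBPJ": ["C2", 4.0, None],
            "NOTCH1": ["C2", 3.0, None],
        },
        "wt_only_markers": {
            # WT-specific boosts: e.g. the CXCL13 axis is stronger in WT
            "CXCL13": ["C2", 4.0, "WT"],
        },
        "coexpression": [
            {"genes": ["RBPJ", "NOTCH1", "ITGAE"], "subset": "C2",
             "group": "WT", "sd": 0.9},
        ],
        "kinetics": {
            "enabled": True,
            # fraction of C2 cells in transit toward C0, per group
            "transit_fraction": {"WT": 0.1, "MT": 0.45},
            "transit_target": "C0",
            "transit_subset": "C2",
            "transit_time_range": [0.1, 1.5],
            "alpha_scale_range": [3.0, 30.0],
            "gamma_range": [0.3, 1.5],
            "subset_scale_sd": 0.25,
        },
        "bulk": {
            "n_samples": 40,
            "designated_subset": "C2",
            "noise_sd": 0.05,
            "slope": 25.0,
            "intercept": -5.0,
        },
    }


def simulate_dataset(scenario: dict | None, seed: int, out_dir) -> dict:
    """Generate and write a full dataset; returns paths plus ground truth."""
    scn = default_scenario()
    scn.update(scenario or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    comp_scn = sim.CompositionScenario.with_fold_changes(
        scn["n_subsets"], scn["group_totals"], scn["mt_folds"]
    )
    labels = sim.gen_composition(comp_scn, seed)

    # gene naming: named genes first, per-subset markers, anonymous filler
    marker_plan: dict = {}
    named = dict(scn.get("named_genes", {}))
    for gene, plan in named.items():
        marker_plan[gene] = [tuple(plan)]
    for gene, plan in scn.get("wt_only_markers", {}).items():
        marker_plan.setdefault(gene, []).append(tuple(plan))
    gene_names = list(marker_plan)
    subsets = comp_scn.subsets
    for subset in subsets:
        for m in range(scn["markers_per_subset"]):
            g = f"MK_{subset}_{m}"
            gene_names.append(g)
            marker_plan[g] = [(subset, scn["marker_fold"])]
    n_filler = max(scn["n_genes"] - len(gene_names), 0)
    gene_names += [f"G{i:05d}" for i in range(n_filler)]
    ac = sim.gen_expression(
        labels, len(gene_names), marker_plan, seed=seed, gene_names=gene_names,
        coexpression_plan=scn.get("coexpression"),
    )
    paths = write_mtx_trio(ac, out)

    truth = {
        "seed": int(seed),
        "proportions": {g: v.tolist() for g, v in comp_scn.proportions.items()},
        "perturbed_subsets": comp_scn.perturbed_subsets,
        "marker_plan": {g: list(p) for g, p in marker_plan.items()},
        "coexpression": scn.get("coexpression", []),
    }

    kin = scn.get("kinetics", {})
    if kin.get("enabled"):
        rng = np.random.default_rng(sim.child_seed(seed, "kinetics-spec"))
        n_kin_genes = min(100, len(gene_names))
        lo_a, hi_a = kin["alpha_scale_range"]
        lo_g, hi_g = kin["gamma_range"]
        alpha = rng.uniform(lo_a, hi_a, n_kin_genes)
        gamma = rng.uniform(lo_g, hi_g, n_kin_genes)
        subset_scale = {
            s: np.exp(rng.normal(0.0, kin.get("subset_scale_sd", 0.25), n_kin_genes))
            for s in subsets
        }
        spl_parts, uns_parts, order = [], [], []
        for grp in ("WT", "MT"):
            sub = labels[labels["group"] == grp]
            spec = sim.KineticsSpec(
                alpha=alpha, gamma=gamma,
                subset_alpha_scale=subset_scale,
                transit={kin["transit_subset"]: (
                    kin["transit_target"], kin["transit_fraction"][grp])},
                transit_time_range=tuple(kin.get("transit_time_range", (0.05, 0.5))),
            )
            s_l, u_l, _ = sim.gen_kinetics(sub, spec, seed=sim.child_seed(seed, f"kin:{grp}"))
            spl_parts.append(s_l)
            uns_parts.append(u_l)
            order.extend(sub.index)
        spliced = sp.hstack(spl_parts).tocsc()
        unspliced = sp.hstack(uns_parts).tocsc()
        # kinetics layers cover the first n_kin_genes; pad with zeros
        pad = sp.csc_matrix((len(gene_names) - n_kin_genes, spliced.shape[1]), dtype=int)
        spliced = sp.vstack([spliced, pad]).tocsc()
        unspliced = sp.vstack([unspliced, pad]).tocsc()
        # reorder columns back to the trio's cell order
        pos = {b: i for i, b in enumerate(order)}
        perm = [pos[b] for b in ac.cell_ids]
        spliced, unspliced = spliced[:, perm], unspliced[:, perm]
        scipy.io.mmwrite(str(out / "spliced.mtx"), sp.coo_matrix(spliced), field="integer")
        scipy.io.mmwrite(str(out / "unspliced.mtx"), sp.coo_matrix(unspliced), field="integer")
        paths["spliced"] = str(out / "spliced.mtx")
        paths["unspliced"] = str(out / "unspliced.mtx")
        truth["kinetics"] = {
            "gamma": gamma.tolist(), "beta": 1.0,
            "transit_fraction": kin["transit_fraction"],
            "transit": [kin["transit_subset"], kin["transit_target"]],
            "n_kinetic_genes": n_kin_genes,
        }

    bulk_cfg = scn.get("bulk")
    if bulk_cfg:
        norm = lognormalize(ac)
        sig = build_signature(norm, ac.cell_meta["cluster"].to_numpy())
        spec = sim.BulkCohortSpec(
            n_samples=bulk_cfg["n_samples"],
            designated_subset=bulk_cfg["designated_subset"],
            noise_sd=bulk_cfg["noise_sd"],
            slope=bulk_cfg["slope"],
            intercept=bulk_cfg["intercept"],
            seed=seed,
        )
        bulk_df, resp, bulk_truth = sim.gen_bulk_cohort(sig.S, spec)
        bulk_df.to_csv(out / "bulk.tsv", sep="\t")
        resp.to_frame().to_csv(out / "response.tsv", sep="\t")
        paths["bulk"] = str(out / "bulk.tsv")
        paths["response"] = str(out / "response.tsv")
        truth["bulk_fractions"] = bulk_truth["fractions"].round(6).to_dict()

    manifest = write_manifest(
        {k: v for k, v in paths.items() if k in
         ("matrix", "features", "barcodes", "meta", "spliced", "unspliced", "embedding")},
        out / "manifest.yaml",
    )
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    paths["manifest"] = manifest
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
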