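"""End-to-end pipeline driver: configuration, stages, report bundle.

The pipeline reads parcel-level inputs (atlas, cohort deformation table,
structural/functional matrices, expression and gene-set files), runs the
analysis stages in order, and writes per-stage TSV outputs plus a single
``summary.json``.  Given identical inputs and seed the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .datatypes import SESSIONS, child_seeds
from .netspread import _weight_matrix, compare_dependent_correlations, node_neighbour_correlation
from .progression import (
    cortical_type_anova,
    progression_map,
    regional_progression_test,
    stack_sessions,
)
from .spins import generate_spins, spin_label_means
from .transcriptomics import celltype_correlations, celltype_scores, genewise_screen, overrepresentation
from .wscore import fit_wscore_model, wscore_cohort

logger = logging.getLogger(__name__)

FOLLOWUPS = tuple(s for s in SESSIONS if s != "baseline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run settings plus input paths."""

    atlas: str = "atlas.tsv"
    cohort: str = "cohort.tsv"
    sc: str = "sc.tsv"
    fc: str = "fc.tsv"
    expression: str = "expression.tsv"
    cell_sets: str = "cell_classes.gmt"
    annotation: str = "annotation.gmt"
    seed: int = 0
    n_spins: int = 1000
    n_perm: int = 1000
    alpha: float = 0.05
    tails: str = "two"
    spin_method: str = "nearest"
    weight_mode: str = "raw_fc"
    fdr_alpha: float = 0.05
    min_term_size: int = 5
    base_dir: str = "."

    def __post_init__(self):
        if self.n_spins < 1:
            raise ValueError("n_spins must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.spin_method not in ("nearest", "bijective"):
            raise ValueError("spin_method must be 'nearest' or 'bijective'")

    def path(self, name: str) -> Path:
        return Path(self.base_dir) / getattr(self, name)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat = {}
        for section in ("data", "run"):
            flat.update(raw.get(section, {}))
        flat.update({k: v for k, v in raw.items() if not isinstance(v, dict)})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**flat)
        if "base_dir" not in flat:
            cfg.base_dir = str(Path(path).parent)
        return cfg


def _load_inputs(config: RunConfig) -> dict:
    atlas = nio.load_atlas(config.path("atlas"))
    return {
        "atlas": atlas,
        "cohort": nio.load_cohort(config.path("cohort"), atlas),
        "connectome": nio.connectome_from_files(config.path("sc"), config.path("fc"), atlas),
        "expression": nio.load_expression(config.path("expression"), atlas),
        "cell_sets": nio.parse_gmt(config.path("cell_sets")),
        "annotation": nio.parse_gmt(config.path("annotation")),
    }


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "n_spins": config.n_spins,
        "n_permutations": config.n_perm,
        "alpha": config.alpha,
        "spin_method": config.spin_method,
        "sex_coding": "0=female,1=male",
    }
    seeds = child_seeds(config.seed, 4)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(name, exc) from exc

    inputs = stage("load", lambda: _load_inputs(config))
    atlas = inputs["atlas"]
    region_ids = list(atlas.region_ids)

    # --- normative model and W-scores -------------------------------------
    def _wscore():
        hc = inputs["cohort"].subset(group="HC", session="baseline")
        model = fit_wscore_model(hc)
        w = wscore_cohort(model, inputs["cohort"])
        pd.DataFrame(
            {
                "region": region_ids,
                "beta_age": model.beta_age,
                "beta_sex": model.beta_sex,
                "beta_intercept": model.beta_intercept,
                "resid_sd": model.resid_sd,
            }
        ).to_csv(out / "wscore_model.tsv", sep="\t", index=False)
        nio.write_cohort(w, out / "wscores.tsv")
        return model, w

    model, w = stage("wscore", _wscore)
    summary["n_controls"] = model.n_controls

    # --- progression maps ---------------------------------------------------
    def _progression_maps():
        maps = {}
        for fu in FOLLOWUPS:
            subjects, y, demo = stack_sessions(w, group="PD", sessions=("baseline", fu))
            maps[fu] = progression_map(y[:, 0, :], y[:, 1, :], aggregate="group-mean")
        df = pd.DataFrame({"region": region_ids, **{f"bl_to_{k}": v for k, v in maps.items()}})
        df.to_csv(out / "progression_maps.tsv", sep="\t", index=False)
        return maps

    prog_maps = stage("progression_maps", _progression_maps)

    # --- regional repeated-measures test ------------------------------------
    def _regional_test():
        subjects, y, demo = stack_sessions(w, group="PD", sessions=SESSIONS)
        res = regional_progression_test(
            y,
            sex=demo["sex"].to_numpy(),
            site=demo["site"].to_numpy(),
            region_ids=region_ids,
            n_perm=config.n_perm,
            seed=seeds[0],
            alpha=config.alpha,
        )
        res.table.to_csv(out / "regional_test.tsv", sep="\t", index=False)
        res.posthoc.to_csv(out / "regional_posthoc.tsv", sep="\t", index=False)
        return res

    regional = stage("regional_test", _regional_test)
    summary["regional_test"] = {
        "n_subjects": regional.n_subjects,
        "n_sig_fwe": int(regional.table["sig_fwe"].sum()),
        "n_sig_fdr": int(regional.table["sig_fdr"].sum()),
    }

    # --- spins (shared across the map-level stages) --------------------------
    spins = stage(
        "spins",
        lambda: generate_spins(atlas, config.n_spins, method=config.spin_method, seed=seeds[1]),
    )
    pd.DataFrame(spins.assignment).to_csv(
        out / "spin_assignments.tsv", sep="\t", index=False, header=False
    )

    # --- cortical-type ANOVA and network label means --------------------------
    def _labels():
        block = {}
        for fu in ("y2", "y4"):
            anova = cortical_type_anova(prog_maps[fu], atlas.cortical_type, alpha=config.alpha)
            net = spin_label_means(prog_maps[fu], atlas.network, spins, tails=config.tails)
            net.to_csv(out / f"network_means_{fu}.tsv", sep="\t", index=False)
            anova.pairwise.to_csv(out / f"cortical_type_posthoc_{fu}.tsv", sep="\t", index=False)
            block[fu] = {
                "cortical_type_F": anova.f,
                "cortical_type_p": anova.p,
                "cortical_type_means": anova.means.to_dict(),
                "network_p_spin": dict(zip(net["label"], net["p_spin"])),
            }
        return block

    summary["labels"] = stage("labels", _labels)

    # --- network-spread analysis ---------------------------------------------
    def _network():
        conn = inputs["connectome"]
        block = {}
        rows = []
        for fu in ("y2", "y4"):
            res = node_neighbour_correlation(
                prog_maps[fu], conn, spins, weight_mode=config.weight_mode, tails=config.tails
            )
            res.insert(0, "interval", f"bl_to_{fu}")
            rows.append(res)
            p_sc, f_sc, _ = _weight_matrix(conn, "fc_weighted_sc", config.weight_mode)
            p_non, f_non, _ = _weight_matrix(conn, "fc_weighted_nonsc", config.weight_mode)
            p_all, f_all, _ = _weight_matrix(conn, "fc_weighted_all", config.weight_mode)
            a = prog_maps[fu]
            mask = ~(f_sc | f_non)
            cmp_non = compare_dependent_correlations(a[mask], (p_sc @ a)[mask], (p_non @ a)[mask])
            mask2 = ~(f_sc | f_all)
            cmp_all = compare_dependent_correlations(a[mask2], (p_sc @ a)[mask2], (p_all @ a)[mask2])
            block[fu] = {
                "r_by_estimator": dict(zip(res["estimator"], res["r"])),
                "p_spin_by_estimator": dict(zip(res["estimator"], res["p_spin"])),
                "zou_ci_sc_vs_nonsc": list(cmp_non["ci"]),
                "zou_ci_sc_vs_all": list(cmp_all["ci"]),
            }
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "network_correlations.tsv", sep="\t", index=False)
        return block

    summary["network"] = stage("network", _network)

    # --- virtual histology ----------------------------------------------------
    def _celltype():
        scores = celltype_scores(inputs["expression"], inputs["cell_sets"])
        scores.to_csv(out / "celltype_scores.tsv", sep="\t", index_label="region_id")
        block = {}
        rows = []
        for fu in ("y2", "y4"):
            cc = celltype_correlations(scores, prog_maps[fu], spins, tails=config.tails)
            cc.insert(0, "interval", f"bl_to_{fu}")
            rows.append(cc)
            block[fu] = dict(zip(cc["cell_class"], cc["r"]))
        pd.concat(rows, ignore_index=True).to_csv(
            out / "celltype_correlations.tsv", sep="\t", index=False
        )
        return block

    summary["celltype_r"] = stage("celltype", _celltype)

    # --- gene screen and overrepresentation -----------------------------------
    def _enrich():
        block = {}
        for fu in ("y2", "y4"):
            screen = genewise_screen(
                inputs["expression"], prog_maps[fu], spins, fdr_alpha=config.fdr_alpha
            )
            screen.table.to_csv(out / f"gene_screen_{fu}.tsv", sep="\t", index=False)
            background = list(inputs["expression"].columns)
            sub = {}
            for direction, target in (("positive", screen.positive), ("negative", screen.negative)):
                if target:
                    enr = overrepresentation(
                        target, background, inputs["annotation"], config.min_term_size
                    )
                    enr.to_csv(out / f"enrichment_{fu}_{direction}.tsv", sep="\t", index=False)
                    sub[direction] = {
                        "n_genes": len(target),
                        "n_sig_terms": int((enr["p_bonf"] < config.alpha).sum()) if len(enr) else 0,
                        "top_term": str(enr["term"].iloc[0]) if len(enr) else None,
                    }
                else:
                    sub[direction] = {"n_genes": 0, "n_sig_terms": 0, "top_term": None}
            block[fu] = sub
        return block

    summary["gene_screen"] = stage("enrich", _enrich)

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
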