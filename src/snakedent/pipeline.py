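"""Full-analysis orchestration over a study bundle.

A bundle directory holds ``tree.nwk``, ``tooth_rows.csv``, optionally
``ecology.csv`` and ``taxa.csv`` (family/subfamily membership and
colubrid / front-fanged flags).  :func:`run_full_analysis` executes the
analysis sequence —

1. derive species-level dental traits;
2. PIC regressions of each focal trait on cranium length; traits that
   scale significantly are replaced by phylogenetic (GLS) residuals;
3. phylogenetic signal table (lambda and K with p-values);
4. phylogenetic PCA: all species on the five focal traits, and per
   colubrid subfamily with fang size replaced by RPTL;
5. colubrid-only PGLS among dental trait pairs;
6. simulation-null phylogenetic ANOVAs by prey-subjugation mode (plus
   the family-level palatine/pterygoid comparisons);
7. diet analyses: diet graph, dissimilarity matrices, phylogenetic
   Mantel test, main-prey ANOVAs;
8. ancestral fang-state reconstruction under 3- and 4-state codings,
   by ML (equal-rates marginals) and threshold-model MCMC —

and writes a machine-readable manifest.  Every stochastic stage's seed is
derived deterministically from the master seed, so re-running a bundle
with the same config reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import asr as asr_mod
from . import ecology as eco_mod
from . import stats as stats_mod
from . import traits as traits_mod
from .tree import Phylogeny, prune_to_taxa, read_newick

__all__ = ["PipelineConfig", "RunManifest", "apply_study_filters", "run_full_analysis"]

FOCAL_TRAITS = [
    "log_n_maxillary_teeth",
    "maxilla_length_mm",
    "largest_tooth_position",
    "fang_size_mm",
    "mean_groove_width_mm",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    seed: int = 0
    alpha: float = 0.05
    nsim: int = 1000
    nperm: int = 999
    asr_ngen: int = 100_000
    asr_burnin: int = 20_000
    lambda_mode: str = "fixed1"
    ppca_mode: str = "covariance"
    diet_metric: str = "euclidean"
    mantel_scheme: str = "phylo"
    diet_normalize: bool = True
    transform_order: str = "transform-first"  # or "residual-first" for fang size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class FilterLog:
    """Record of species removed by the study filters."""

    removed_unknown_mode: list[str] = field(default_factory=list)
    removed_single_species_families: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_unknown_mode": self.removed_unknown_mode,
            "removed_single_species_families": self.removed_single_species_families,
        }


def apply_study_filters(
    ecology: pd.DataFrame | None, taxa: pd.DataFrame | None = None
) -> tuple[pd.DataFrame | None, pd.DataFrame | None, FilterLog]:
    """Apply the study's exclusion rules.

    Species whose prey-subjugation mode could not be determined
    ("unknown" or missing) are removed from mode-based analyses, and
    families represented by a single species are removed from the
    family-level tooth-count comparisons.  Returns (filtered ecology,
    filtered taxa, filter log).
    """
    log = FilterLog()
    eco_f = None
    if ecology is not None:
        known = ecology["mode"].isin(eco_mod.SUBJUGATION_MODES)
        log.removed_unknown_mode = sorted(ecology.index[~known])
        eco_f = ecology[known].copy()
    taxa_f = None
    if taxa is not None:
        sizes = taxa["family"].value_counts()
        single = sizes[sizes < 2].index
        for fam in single:
            log.removed_single_species_families[fam] = sorted(
                taxa.index[taxa["family"] == fam]
            )
        taxa_f = taxa[~taxa["family"].isin(single)].copy()
    return eco_f, taxa_f, log


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    inputs: dict[str, str]
    species_dropped_from_tree: list[str]
    filter_log: dict
    stages: list[dict]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, index: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def _collect_warnings(wlist) -> list[str]:
    return sorted({str(w.message) for w in wlist})


def run_full_analysis(
    bundle_dir, config: PipelineConfig | dict | None = None, out_dir=None
) -> RunManifest:
    """Run the complete analysis over a bundle directory.

    Species present in the tables but absent from the tree are dropped
    with a logged list; missing ecology data causes the mode-ANOVA and
    diet stages to be skipped with explicit SKIPPED status.  Returns the
    manifest (also written to ``<out_dir>/manifest.json``).
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    bundle = Path(bundle_dir)
    out = Path(out_dir) if out_dir is not None else bundle / "results"
    out.mkdir(parents=True, exist_ok=True)

    # ---- load and validate all inputs up front ------------------------
    tree_path = bundle / "tree.nwk"
    tooth_path = bundle / "tooth_rows.csv"
    eco_path = bundle / "ecology.csv"
    taxa_path = bundle / "taxa.csv"
    if not tree_path.exists():
        raise FileNotFoundError(f"bundle is missing tree.nwk: {bundle}")
    if not tooth_path.exists():
        raise FileNotFoundError(f"bundle is missing tooth_rows.csv: {bundle}")
    tree_full = read_newick(tree_path)
    tooth_rows = traits_mod.read_tooth_table(tooth_path)
    ecology = eco_mod.read_ecology_table(eco_path) if eco_path.exists() else None
    taxa = (
        pd.read_csv(taxa_path).set_index("species") if taxa_path.exists() else None
    )
    inputs = {
        p.name: _sha256(p)
        for p in (tree_path, tooth_path, eco_path, taxa_path)
        if p.exists()
    }

    stages: list[dict] = []
    seed = config.seed

    def record(name, status, params=None, outputs=None, results=None, warns=None, stage_seed=None):
        stages.append(
            {
                "name": name,
                "status": status,
                "seed": stage_seed,
                "params": params or {},
                "outputs": {f: _sha256(out / f) for f in (outputs or [])},
                "results": results or {},
                "warnings": warns or [],
            }
        )

    # ---- stage 1: derive traits ---------------------------------------
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        trait_df = traits_mod.trait_table(tooth_rows)
    table_species = set(trait_df.index)
    tree_species = set(tree_full.tip_labels)
    dropped = sorted(table_species - tree_species)
    analysis_species = [s for s in tree_full.tip_labels if s in table_species]
    tree = prune_to_taxa(tree_full, analysis_species)
    trait_df = trait_df.loc[tree.tip_labels]
    if ecology is not None:
        ecology = ecology.loc[[s for s in tree.tip_labels if s in ecology.index]]
    trait_df.to_csv(out / "traits.csv")
    rptl_undefined = sorted(trait_df.index[trait_df["rptl_mm"].isna()])
    record(
        "derive_traits",
        "completed",
        outputs=["traits.csv"],
        results={"n_species": len(trait_df), "rptl_undefined": rptl_undefined},
        warns=_collect_warnings(wlist),
    )

    if taxa is not None:
        taxa = taxa.loc[[s for s in tree.tip_labels if s in taxa.index]]
        colubrids = sorted(taxa.index[taxa["is_colubrid"].astype(bool)])
    else:
        colubrids = list(tree.tip_labels)

    # analyzed scale of fang size: log first by default
    fang = trait_df["fang_size_mm"]
    if config.transform_order == "transform-first":
        trait_df = trait_df.assign(fang_size_analyzed=np.log(fang))
    else:
        trait_df = trait_df.assign(fang_size_analyzed=fang)

    # ---- stage 2: PIC size screen + phylogenetic residuals -------------
    analyzed: dict[str, pd.Series] = {}
    screen_rows = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        cranium = trait_df["cranium_length_mm"]
        screen_specs = [(t, list(tree.tip_labels)) for t in FOCAL_TRAITS]
        screen_specs.append(("rptl_mm", colubrids))
        for trait_name, subset in screen_specs:
            col = "fang_size_analyzed" if trait_name == "fang_size_mm" else trait_name
            vals = trait_df.loc[[s for s in subset if s in trait_df.index], col].dropna()
            if len(vals) < 4:
                screen_rows.append(
                    {"trait": trait_name, "n": len(vals), "status": "too-few-species"}
                )
                continue
            sub_tree = (
                prune_to_taxa(tree, list(vals.index))
                if len(vals) < len(tree.tip_labels)
                else tree
            )
            vals = vals.loc[sub_tree.tip_labels]
            cran = cranium.loc[sub_tree.tip_labels]
            reg = stats_mod.pic_regression(
                stats_mod.pic(sub_tree, cran), stats_mod.pic(sub_tree, vals)
            )
            corrected = reg.p_value < config.alpha
            if corrected:
                analyzed[trait_name] = stats_mod.phyl_resid(sub_tree, vals, cran)
            else:
                analyzed[trait_name] = vals
            screen_rows.append(
                {
                    "trait": trait_name,
                    "n": len(vals),
                    "slope": reg.slope,
                    "F": reg.F,
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "size_corrected": corrected,
                    "status": "ok",
                }
            )
    screen_df = pd.DataFrame(screen_rows).set_index("trait")
    screen_df.to_csv(out / "size_correction.csv")
    record(
        "size_screen",
        "completed",
        params={"alpha": config.alpha},
        outputs=["size_correction.csv"],
        results={
            "size_corrected": sorted(
                t for t in screen_df.index if screen_df.loc[t].get("size_corrected") is True
            )
        },
        warns=_collect_warnings(wlist),
    )

    # ---- stage 3: phylogenetic signal ----------------------------------
    s3 = _stage_seed(seed, 3)
    signal_rows = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for i, (trait_name, vals) in enumerate(sorted(analyzed.items())):
            sub_tree = (
                prune_to_taxa(tree, list(vals.index))
                if len(vals) < len(tree.tip_labels)
                else tree
            )
            res = stats_mod.phylo_signal(
                sub_tree,
                vals.loc[sub_tree.tip_labels],
                nperm=config.nperm,
                seed=_stage_seed(s3, i),
                trait_name=trait_name,
            )
            signal_rows.append(res.to_dict())
    pd.DataFrame(signal_rows).set_index("trait").to_csv(out / "signal_table.csv")
    record(
        "phylogenetic_signal",
        "completed",
        params={"nperm": config.nperm},
        outputs=["signal_table.csv"],
        stage_seed=s3,
        warns=_collect_warnings(wlist),
    )

    # ---- stage 4: pPCA --------------------------------------------------
    def ppca_on(species_list, trait_names, tag):
        vals = pd.DataFrame(
            {t: analyzed[t] for t in trait_names if t in analyzed}
        ).loc[[s for s in species_list if s in trait_df.index]]
        if "mean_groove_width_mm" in vals.columns:
            # species without grooves have no groove: width 0 on the trait scale
            vals["mean_groove_width_mm"] = vals["mean_groove_width_mm"].fillna(0.0)
        vals = vals.dropna()
        const = [c for c in vals.columns if vals[c].nunique() <= 1]
        vals = vals.drop(columns=const)
        if len(vals) < 4 or vals.shape[1] < 2:
            return None, f"{tag}: too few species or traits for pPCA"
        sub_tree = (
            prune_to_taxa(tree, list(vals.index))
            if len(vals) < len(tree.tip_labels)
            else tree
        )
        res = stats_mod.ppca(sub_tree, vals.loc[sub_tree.tip_labels], mode=config.ppca_mode)
        res.loadings.to_csv(out / f"ppca_{tag}_loadings.csv")
        res.scores.to_csv(out / f"ppca_{tag}_scores.csv")
        return res, None

    ppca_outputs, ppca_notes = [], []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        res_all, note = ppca_on(list(tree.tip_labels), FOCAL_TRAITS, "all")
        if note:
            ppca_notes.append(note)
        else:
            ppca_outputs += ["ppca_all_loadings.csv", "ppca_all_scores.csv"]
        subfams = (
            sorted(set(taxa["subfamily"].dropna()) - {""}) if taxa is not None else []
        )
        sub_traits = [t for t in FOCAL_TRAITS if t != "fang_size_mm"] + ["rptl_mm"]
        for sf in subfams:
            members = sorted(taxa.index[taxa["subfamily"] == sf])
            _, note = ppca_on(members, sub_traits, sf)
            if note:
                ppca_notes.append(note)
            else:
                ppca_outputs += [f"ppca_{sf}_loadings.csv", f"ppca_{sf}_scores.csv"]
    record(
        "ppca",
        "completed",
        params={"mode": config.ppca_mode},
        outputs=ppca_outputs,
        results={"notes": ppca_notes},
        warns=_collect_warnings(wlist),
    )

    # ---- stage 5: colubrid-only PGLS ------------------------------------
    pgls_rows = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        pairs = [
            ("log_n_maxillary_teeth", "maxilla_length_mm"),
            ("rptl_mm", "maxilla_length_mm"),
            ("log_n_maxillary_teeth", "rptl_mm"),
        ]
        for resp, pred in pairs:
            if resp not in analyzed or pred not in analyzed:
                continue
            joint = pd.DataFrame(
                {"y": analyzed[resp], "x": analyzed[pred]}
            ).loc[[s for s in colubrids if s in analyzed[resp].index]].dropna()
            if len(joint) < 4:
                continue
            sub_tree = prune_to_taxa(tree, list(joint.index))
            res = stats_mod.pgls(
                sub_tree,
                joint["y"].loc[sub_tree.tip_labels],
                joint["x"].loc[sub_tree.tip_labels],
                lambda_mode=config.lambda_mode,
                response=resp,
                predictor=pred,
            )
            pgls_rows.append({**res.to_dict(), "n": len(joint)})
    pd.DataFrame(pgls_rows).to_csv(out / "pgls_colubrids.csv", index=False)
    record(
        "pgls_colubrids",
        "completed",
        params={"lambda_mode": config.lambda_mode},
        outputs=["pgls_colubrids.csv"],
        warns=_collect_warnings(wlist),
    )

    # ---- study filters (needed by stages 6-7) ---------------------------
    eco_f, taxa_f, flog = apply_study_filters(ecology, taxa)

    # ---- stage 6: phylANOVA by prey-subjugation mode --------------------
    s6 = _stage_seed(seed, 6)
    if ecology is None:
        record("mode_anova", "skipped", results={"reason": "no ecology table"})
    else:
        anova_rows = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            specs = [
                ("log_n_maxillary_teeth", list(eco_f.index)),
                ("maxilla_length_mm", list(eco_f.index)),
                ("fang_size_mm", list(eco_f.index)),
                ("largest_tooth_position", list(eco_f.index)),
                ("rptl_mm", [s for s in colubrids if s in eco_f.index]),
            ]
            for i, (trait_name, subset) in enumerate(specs):
                if trait_name not in analyzed:
                    continue
                joint = pd.DataFrame(
                    {"value": analyzed[trait_name]}
                ).loc[[s for s in subset if s in analyzed[trait_name].index]].dropna()
                modes = eco_f.loc[joint.index, "mode"]
                sizes = modes.value_counts()
                keep_modes = sizes[sizes >= 2].index
                joint = joint[modes.isin(keep_modes)]
                modes = modes.loc[joint.index]
                if len(joint) < 8 or modes.nunique() < 2:
                    continue
                sub_tree = prune_to_taxa(tree, list(joint.index))
                res = stats_mod.phyl_anova(
                    sub_tree,
                    joint["value"].loc[sub_tree.tip_labels],
                    modes.loc[sub_tree.tip_labels],
                    nsim=config.nsim,
                    posthoc=True,
                    seed=_stage_seed(s6, i),
                    grouping="subjugation_mode",
                )
                res.posthoc_t.to_csv(out / f"anova_mode_{trait_name}_posthoc_t.csv")
                res.posthoc_p.to_csv(out / f"anova_mode_{trait_name}_posthoc_p.csv")
                anova_rows.append(
                    {
                        "trait": trait_name,
                        "n": len(joint),
                        "F": res.F,
                        "p_value": res.p_value,
                        "group_means": json.dumps(res.group_means, sort_keys=True),
                    }
                )
            # family-level comparisons of the inner tooth rows
            fam_rows = []
            if taxa_f is not None:
                for i, col in enumerate(("n_palatine_teeth", "n_pterygoid_teeth")):
                    joint = trait_df.loc[
                        [s for s in taxa_f.index if s in trait_df.index], col
                    ].dropna()
                    fams = taxa_f.loc[joint.index, "family"]
                    if len(joint) < 8 or fams.nunique() < 2:
                        continue
                    sub_tree = prune_to_taxa(tree, list(joint.index))
                    res = stats_mod.phyl_anova(
                        sub_tree,
                        joint.loc[sub_tree.tip_labels],
                        fams.loc[sub_tree.tip_labels],
                        nsim=config.nsim,
                        posthoc=False,
                        seed=_stage_seed(s6, 100 + i),
                        grouping="family",
                    )
                    fam_rows.append(
                        {"trait": col, "n": len(joint), "F": res.F, "p_value": res.p_value}
                    )
        pd.DataFrame(anova_rows).to_csv(out / "anova_mode.csv", index=False)
        pd.DataFrame(fam_rows).to_csv(out / "anova_family.csv", index=False)
        outputs = ["anova_mode.csv", "anova_family.csv"] + [
            f for f in sorted(p.name for p in out.iterdir())
            if f.startswith("anova_mode_") and f.endswith(".csv")
        ]
        record(
            "mode_anova",
            "completed",
            params={"nsim": config.nsim},
            outputs=outputs,
            results={
                "n_species_mode_analyses": int(len(eco_f)),
                "n_removed_unknown_mode": len(flog.removed_unknown_mode),
            },
            stage_seed=s6,
            warns=_collect_warnings(wlist),
        )

    # ---- stage 7: diet --------------------------------------------------
    s7 = _stage_seed(seed, 7)
    if ecology is None:
        record("diet", "skipped", results={"reason": "no ecology table"})
    else:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            counts = ecology[eco_mod.DIET_CATEGORIES]
            has_diet = counts.sum(axis=1) > 0
            diet_species = sorted(ecology.index[has_diet])
            G = eco_mod.build_diet_graph(ecology.loc[diet_species])
            edges = pd.DataFrame(
                [(u, v, d["weight"]) for u, v, d in sorted(G.edges(data=True))],
                columns=["species", "prey_category", "weight"],
            )
            edges.to_csv(out / "diet_graph_edges.csv", index=False)
            nx.write_graphml(G, out / "diet_graph.graphml")

            dent_cols = [
                t
                for t in ("log_n_maxillary_teeth", "maxilla_length_mm",
                          "largest_tooth_position", "fang_size_mm")
                if t in analyzed
            ]
            dent = pd.DataFrame({t: analyzed[t] for t in dent_cols}).loc[
                [s for s in diet_species if s in trait_df.index]
            ].dropna()
            dent_std = (dent - dent.mean()) / dent.std()
            diet_vals = counts.loc[dent_std.index]
            if config.diet_normalize:
                diet_vals = diet_vals.div(diet_vals.sum(axis=1), axis=0)
            D_dent = eco_mod.dissimilarity_matrix(dent_std, metric=config.diet_metric)
            D_diet = eco_mod.dissimilarity_matrix(diet_vals, metric="euclidean")
            sub_tree = prune_to_taxa(tree, list(dent_std.index))
            order = sub_tree.tip_labels
            D_dent = D_dent.loc[order, order]
            D_diet = D_diet.loc[order, order]
            mantel_phylo = eco_mod.phylo_mantel(
                sub_tree, D_dent, D_diet, nperm=config.nperm,
                scheme=config.mantel_scheme, seed=_stage_seed(s7, 0),
            )
            mantel_free = eco_mod.phylo_mantel(
                sub_tree, D_dent, D_diet, nperm=config.nperm,
                scheme="free", seed=_stage_seed(s7, 1),
            )

            main_prey = {}
            for sp in diet_species:
                main_prey[sp] = eco_mod.main_prey_item(ecology.loc[sp, eco_mod.DIET_CATEGORIES])
            prey_ser = pd.Series(main_prey)
            prey_rows = []
            for i, trait_name in enumerate(dent_cols):
                joint = pd.DataFrame({"value": analyzed[trait_name]}).loc[
                    [s for s in diet_species if s in analyzed[trait_name].index]
                ].dropna()
                groups = prey_ser.loc[joint.index]
                sizes = groups.value_counts()
                keep = sizes[sizes >= 2].index
                joint = joint[groups.isin(keep)]
                groups = groups.loc[joint.index]
                if len(joint) < 8 or groups.nunique() < 2:
                    continue
                sub_t = prune_to_taxa(tree, list(joint.index))
                res = stats_mod.phyl_anova(
                    sub_t,
                    joint["value"].loc[sub_t.tip_labels],
                    groups.loc[sub_t.tip_labels],
                    nsim=config.nsim,
                    posthoc=True,
                    seed=_stage_seed(s7, 10 + i),
                    grouping="main_prey",
                )
                res.posthoc_p.to_csv(out / f"anova_prey_{trait_name}_posthoc_p.csv")
                prey_rows.append(
                    {"trait": trait_name, "n": len(joint), "F": res.F, "p_value": res.p_value}
                )
            pd.DataFrame(prey_rows).to_csv(out / "anova_main_prey.csv", index=False)
            with open(out / "mantel.json", "w") as fh:
                json.dump(
                    {"phylo": mantel_phylo.to_dict(), "free": mantel_free.to_dict()},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
        outputs = ["diet_graph_edges.csv", "diet_graph.graphml", "mantel.json",
                   "anova_main_prey.csv"] + [
            f for f in sorted(p.name for p in out.iterdir())
            if f.startswith("anova_prey_")
        ]
        record(
            "diet",
            "completed",
            params={
                "nperm": config.nperm,
                "metric": config.diet_metric,
                "scheme": config.mantel_scheme,
                "diet_normalize": config.diet_normalize,
            },
            outputs=outputs,
            results={
                "n_species_with_diet": len(diet_species),
                "mantel_r_phylo": mantel_phylo.r,
                "mantel_p_phylo": mantel_phylo.p_value,
                "mantel_r_free": mantel_free.r,
                "mantel_p_free": mantel_free.p_value,
            },
            stage_seed=s7,
            warns=_collect_warnings(wlist),
        )

    # ---- stage 8: ancestral fang-state reconstruction -------------------
    s8 = _stage_seed(seed, 8)
    if ecology is None or "fang_state" not in (ecology.columns if ecology is not None else []):
        record("asr", "skipped", results={"reason": "no fang states available"})
    else:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            fang4 = ecology["fang_state"].dropna()
            species = [s for s in tree.tip_labels if s in fang4.index]
            sub_tree = prune_to_taxa(tree, species) if len(species) < len(tree.tip_labels) else tree
            fang4 = fang4.loc[sub_tree.tip_labels]
            fang3 = fang4.replace({"tubular": "hollow"})
            asr_results = {}
            outputs = []
            for tag, tips, states in (
                ("3state", fang3, eco_mod.FANG_STATES_3),
                ("4state", fang4, eco_mod.FANG_STATES_4),
            ):
                present = [st for st in states if st in set(tips)]
                ml = asr_mod.ml_asr_marginal(sub_tree, tips.to_dict(), states=present)
                ml.to_csv(out / f"asr_ml_{tag}.csv")
                with open(out / f"asr_ml_{tag}.nwk", "w") as fh:
                    fh.write(ml.annotated_newick(sub_tree) + "\n")
                mc = asr_mod.ancthresh_mcmc(
                    sub_tree,
                    tips.to_dict(),
                    state_order=present,
                    ngen=config.asr_ngen,
                    burnin=config.asr_burnin,
                    seed=_stage_seed(s8, 0 if tag == "3state" else 1),
                )
                mc.to_csv(out / f"asr_threshold_{tag}.csv")
                mc.chain.trace.to_csv(out / f"asr_threshold_{tag}_trace.csv", index=False)
                root_id = ml.node_probabilities.index[-1]
                asr_results[tag] = {
                    "q_ml": ml.q,
                    "logL_ml": ml.log_likelihood,
                    "root_marginal_ml": ml.node_probabilities.loc[root_id].to_dict(),
                    "root_posterior_threshold": mc.node_probabilities.loc[root_id].to_dict(),
                    "rhat_root": mc.chain.rhat_root,
                }
                outputs += [
                    f"asr_ml_{tag}.csv", f"asr_ml_{tag}.nwk",
                    f"asr_threshold_{tag}.csv", f"asr_threshold_{tag}_trace.csv",
                ]
        record(
            "asr",
            "completed",
            params={"ngen": config.asr_ngen, "burnin": config.asr_burnin},
            outputs=outputs,
            results=asr_results,
            stage_seed=s8,
            warns=_collect_warnings(wlist),
        )

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=hashlib.sha256(config_json.encode()).hexdigest(),
        seed=seed,
        inputs=inputs,
        species_dropped_from_tree=dropped,
        filter_log=flog.to_dict(),
        stages=stages,
    )
    manifest.write(out / "manifest.json")
    return manifest
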