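"""End-to-end orchestration: simulate, analyze, recover.

The analysis runs the comparative stages in a fixed order — anatomy
allometry, SMA slope comparisons, PRS relationships, nonlinear trait fits
(overall and per group), phylogenetic statistics, data-source analysis —
and assembles a single JSON report validated against the pydantic models
below (their JSON schema ships in-repo as ``report_schema.json``).  Every
run writes a manifest with the config hash, master seed and SHA-256 of
each output file: identical config and seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .allometry import TissueMixture
from .groups import (
    data_source_analysis,
    exclude_outliers,
    fit_by_group,
    interaction_test,
)
from .phylo import (
    blomberg_k,
    pagel_lambda_ml,
    pgls,
    pic_regression,
    read_newick,
    reconcile_species,
    resolve_polytomies,
    write_newick,
)
from .regression import (
    fit_anatomy_allometry,
    nls_allometric_fit,
    ols_fit,
    sma_common_slope_test,
)
from .synthetic import (
    GeneratorConfig,
    GroupConfig,
    aggregate_species_means,
    generate_dataset,
)

__all__ = [
    "StageReport",
    "AnalysisReport",
    "RunManifest",
    "config_to_flat",
    "config_from_flat",
    "read_config",
    "write_config",
    "run_simulate",
    "run_analysis",
    "run_recovery",
    "recovery_table",
]

MAIN_MYCORRHIZAL_TYPES = ["AM", "EM", "ERM"]
MIN_PHYLO_OVERLAP = 4
MIN_PRS_RN_N = 15  # below this the PRS-RN regression is skipped, logged


# --------------------------------------------------------------------------
# report & manifest models


class StageReport(BaseModel):
    status: Literal["ok", "skipped", "error"]
    reason: Optional[str] = None
    n_in: Optional[int] = None
    n_out: Optional[int] = None
    results: dict = Field(default_factory=dict)


class AnalysisReport(BaseModel):
    package_version: str
    seed: Optional[int] = None
    method_notes: list[str] = Field(default_factory=list)
    stages: dict[str, StageReport] = Field(default_factory=dict)


class ManifestStage(BaseModel):
    name: str
    n_in: int
    n_out: int
    seconds: float


class RunManifest(BaseModel):
    config_hash: str
    master_seed: int
    software_version: str
    created_utc: str
    stages: list[ManifestStage] = Field(default_factory=list)
    outputs: dict[str, str] = Field(default_factory=dict)  # filename -> sha256


# --------------------------------------------------------------------------
# flat key-value config I/O


def _flatten(prefix: str, obj) -> dict[str, str]:
    out: dict[str, str] = {}
    if dataclasses.is_dataclass(obj):
        for f in dataclasses.fields(obj):
            out.update(_flatten(f"{prefix}{f.name}.", getattr(obj, f.name)))
    elif isinstance(obj, dict):
        for key, val in sorted(obj.items()):
            out[f"{prefix}{key}"] = str(val)
    else:
        out[prefix.rstrip(".")] = "none" if obj is None else str(obj)
    return out


def config_to_flat(config: GeneratorConfig) -> dict[str, str]:
    flat = _flatten("", config)
    return {k.replace("mycorrhiza_counts", "mycorrhiza"): v for k, v in flat.items()}


def _convert(value: str, typ) -> object:
    # dataclass field types are plain strings under deferred annotations
    name = typ if isinstance(typ, str) else getattr(typ, "__name__", str(typ))
    if value == "none":
        return None
    if "bool" in name:
        return value.lower() in ("1", "true", "yes")
    if "int" in name:
        return int(value)
    if "float" in name:
        return float(value)
    return value


def config_from_flat(flat: dict[str, str]) -> GeneratorConfig:
    """Build a config from dotted ``key=value`` pairs over the defaults.

    Unknown keys raise with the full list; ``seed`` is mandatory.
    """
    if "seed" not in flat:
        raise ValueError("seed is mandatory in the generator config")
    config = GeneratorConfig(seed=int(flat["seed"]))
    top_fields = {f.name: f for f in dataclasses.fields(GeneratorConfig)}
    group_fields = {f.name: f for f in dataclasses.fields(GroupConfig)}
    mix_fields = {f.name: f for f in dataclasses.fields(TissueMixture)}
    unknown: list[str] = []
    mixture_updates: dict[str, float] = {}
    for key, value in flat.items():
        if key == "seed":
            continue
        parts = key.split(".")
        if len(parts) == 1:
            if key in top_fields and key not in ("woody", "nonwoody", "mixture"):
                setattr(config, key, _convert(value, top_fields[key].type))
            else:
                unknown.append(key)
        elif parts[0] in ("woody", "nonwoody"):
            group = getattr(config, parts[0])
            if len(parts) == 3 and parts[1] == "mycorrhiza":
                group.mycorrhiza_counts[parts[2]] = int(value)
            elif len(parts) == 2 and parts[1] in group_fields:
                setattr(group, parts[1], _convert(value, group_fields[parts[1]].type))
            else:
                unknown.append(key)
        elif parts[0] == "mixture" and len(parts) == 2 and parts[1] in mix_fields:
            mixture_updates[parts[1]] = float(value)
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if mixture_updates:
        config.mixture = dataclasses.replace(config.mixture, **mixture_updates)
    config.validate()
    return config


def read_config(path: str | Path) -> GeneratorConfig:
    flat: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        flat[key.strip()] = value.strip()
    return config_from_flat(flat)


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    flat = config_to_flat(config)
    lines = [f"{k} = {v}" for k, v in sorted(flat.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(config: GeneratorConfig) -> str:
    canon = json.dumps(config_to_flat(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# --------------------------------------------------------------------------
# simulate


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_traits_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    required = {"species", "diameter"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traits CSV missing columns: {sorted(missing)}")
    bad = df.index[df["diameter"].notna() & (df["diameter"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive diameter at CSV row(s) {list(bad[:5] + 2)} "
            f"(column 'diameter')"
        )
    return df


def run_simulate(config: GeneratorConfig, out_dir: str | Path) -> RunManifest:
    """Generate a dataset and write traits.csv, tree.nwk, truth.json, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    table, tree, truth = generate_dataset(config)
    elapsed = time.perf_counter() - t0
    write_traits_csv(table, out / "traits.csv")
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    write_config(config, out / "config.txt")
    manifest = RunManifest(
        config_hash=config_hash(config),
        master_seed=config.seed,
        software_version=__version__,
        created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        stages=[
            ManifestStage(
                name="simulate", n_in=0, n_out=len(table), seconds=round(elapsed, 4)
            )
        ],
        outputs={
            name: _sha256(out / name)
            for name in ("traits.csv", "tree.nwk", "truth.json", "config.txt")
        },
    )
    (out / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest


# --------------------------------------------------------------------------
# analysis stages


def _stage_anatomy(table: pd.DataFrame) -> StageReport:
    anat = table.dropna(subset=["diameter", "tToS", "SR"])
    results: dict = {"by_growth_form": {}, "sma": {}}
    groups: dict[str, pd.DataFrame] = {}
    for form, sub in anat.groupby("growth_form"):
        if len(sub) < 3:
            results["by_growth_form"][form] = {"skipped": f"n={len(sub)} < 3"}
            continue
        groups[form] = sub
        params, ttos_fit = fit_anatomy_allometry(sub["diameter"], sub["tToS"])
        sr_fit = ols_fit(sub["diameter"], sub["SR"])
        results["by_growth_form"][form] = {
            "allometry": {"k": params.k, "c": params.c},
            "ttos_fit": ttos_fit.to_dict(),
            "sr_fit": sr_fit.to_dict(),
        }
    # SMA slope comparisons: tToS vs SR within form, and forms against each other
    for form, sub in groups.items():
        test = sma_common_slope_test(
            [(sub["diameter"], sub["tToS"]), (sub["diameter"], sub["SR"])],
            seed=0,
        )
        results["sma"][f"ttos_vs_sr_{form}"] = test.to_dict()
    if len(groups) == 2:
        for resp in ("tToS", "SR"):
            test = sma_common_slope_test(
                [(sub["diameter"], sub[resp]) for sub in groups.values()],
                seed=0,
            )
            results["sma"][f"{resp}_across_growth_forms"] = test.to_dict()
    return StageReport(
        status="ok", n_in=len(table), n_out=len(anat), results=results
    )


def _stage_prs(table: pd.DataFrame) -> StageReport:
    anat = table.dropna(subset=["diameter", "PRS"])
    kept, log = exclude_outliers(anat)
    results: dict = {
        "excluded": log.to_dict(orient="records"),
        "prs_vs_diameter": {},
        "trait_vs_prs": {},
    }
    for form, sub in kept.groupby("growth_form"):
        if len(sub) >= 10:
            results["prs_vs_diameter"][form] = nls_allometric_fit(
                sub["diameter"], sub["PRS"]
            ).to_dict()
        for resp in ("RTD", "RN"):
            pair = sub.dropna(subset=[resp, "PRS"])
            key = f"{resp}_{form}"
            if len(pair) < MIN_PRS_RN_N:
                results["trait_vs_prs"][key] = {
                    "skipped": f"n={len(pair)} < {MIN_PRS_RN_N}"
                }
                continue
            results["trait_vs_prs"][key] = ols_fit(pair["PRS"], pair[resp]).to_dict()
    return StageReport(
        status="ok", n_in=len(anat), n_out=len(kept), results=results
    )


def _stage_nonlinear(table: pd.DataFrame) -> StageReport:
    results: dict = {}
    data = table.dropna(subset=["diameter"])
    for resp in ("RTD", "RN"):
        sub = data.dropna(subset=[resp])
        block: dict = {}
        if len(sub) >= 10:
            block["all_species"] = nls_allometric_fit(
                sub["diameter"], sub[resp]
            ).to_dict()
        block["by_growth_form"] = fit_by_group(
            sub, y=resp, grouping="growth_form"
        ).to_dict()
        woody = sub[sub["growth_form"] == "woody"]
        if len(woody):
            main = woody[woody["mycorrhiza"].isin(MAIN_MYCORRHIZAL_TYPES)]
            if main["mycorrhiza"].nunique() >= 1:
                block["woody_by_mycorrhiza"] = fit_by_group(
                    main, y=resp, grouping="mycorrhiza"
                ).to_dict()
            if woody["root_sampling"].nunique() >= 2:
                block["woody_by_root_sampling"] = fit_by_group(
                    woody, y=resp, grouping="root_sampling"
                ).to_dict()
        results[resp] = block
    return StageReport(status="ok", n_in=len(table), n_out=len(data), results=results)


def _stage_phylo(
    table: pd.DataFrame, tree, n_permutations: int, seed: int
) -> StageReport:
    mapping, unmatched = reconcile_species(table["species"].tolist(), tree)
    data = table[table["species"].isin(mapping)].copy()
    data["tip"] = data["species"].map(mapping)
    if len(data) < MIN_PHYLO_OVERLAP:
        return StageReport(
            status="skipped",
            reason=f"only {len(data)} species overlap the tree "
            f"(need >= {MIN_PHYLO_OVERLAP})",
            n_in=len(table),
            n_out=len(data),
        )
    results: dict = {"n_unmatched_species": len(unmatched), "signals": {}, "pic": {},
                     "pgls": {}}
    subsets = {"all": data}
    for form, sub in data.groupby("growth_form"):
        subsets[str(form)] = sub
    for name, sub in subsets.items():
        if len(sub) < MIN_PHYLO_OVERLAP:
            continue
        subtree = tree.extract_tree_with_taxa_labels(sub["tip"].tolist())
        subtree = resolve_polytomies(subtree, seed=seed)
        sig_block: dict = {}
        pic_block: dict = {}
        for trait_name in ("diameter", "RTD", "RN"):
            vals = sub.dropna(subset=[trait_name]).set_index("tip")[trait_name]
            if vals.size < MIN_PHYLO_OVERLAP or vals.nunique() < 2:
                continue
            trait_tree = subtree.extract_tree_with_taxa_labels(vals.index.tolist())
            trait_tree = resolve_polytomies(trait_tree, seed=seed)
            k_res = blomberg_k(
                trait_tree, vals, n_permutations=n_permutations, seed=seed
            )
            lam_res = pagel_lambda_ml(trait_tree, vals)
            sig_block[trait_name] = {
                "K": k_res.to_dict(),
                "lambda": lam_res.to_dict(),
            }
        for resp in ("RTD", "RN"):
            pair = sub.dropna(subset=["diameter", resp]).set_index("tip")
            if len(pair) < MIN_PHYLO_OVERLAP:
                continue
            pair_tree = subtree.extract_tree_with_taxa_labels(pair.index.tolist())
            pair_tree = resolve_polytomies(pair_tree, seed=seed)
            pic_block[f"{resp}_vs_diameter"] = pic_regression(
                pair_tree, pair["diameter"], pair[resp]
            ).to_dict()
        results["signals"][name] = sig_block
        results["pic"][name] = pic_block
    # PGLS with diameter x growth form interaction on the full overlap
    for resp in ("RTD", "RN"):
        pair = data.dropna(subset=["diameter", resp]).set_index("tip")
        if len(pair) < MIN_PHYLO_OVERLAP or pair["growth_form"].nunique() < 2:
            continue
        sub_tree = tree.extract_tree_with_taxa_labels(pair.index.tolist())
        sub_tree = resolve_polytomies(sub_tree, seed=seed)
        woody_dummy = (pair["growth_form"] == "woody").astype(float)
        X = pd.DataFrame(
            {
                "diameter": pair["diameter"],
                "woody": woody_dummy,
                "diameter_x_woody": pair["diameter"] * woody_dummy,
            },
            index=pair.index,
        )
        results["pgls"][f"{resp}_growth_form_interaction"] = pgls(
            sub_tree, pair[resp], X, correlation="bm"
        ).to_dict()
    return StageReport(status="ok", n_in=len(table), n_out=len(data), results=results)


def _stage_data_source(table: pd.DataFrame) -> StageReport:
    woody = table[table["growth_form"] == "woody"]
    if "data_source_class" not in woody.columns or woody[
        "data_source_class"
    ].isna().all():
        return StageReport(
            status="skipped",
            reason="no data_source_class labels",
            n_in=len(table),
            n_out=0,
        )
    report = data_source_analysis(woody)
    inter = interaction_test(woody, y="RTD", factor="data_source_class")
    return StageReport(
        status="ok",
        n_in=len(table),
        n_out=len(woody),
        results={
            "data_source": report.to_dict(),
            "interaction_rtd": inter.to_dict(),
        },
    )


def run_analysis(
    table: pd.DataFrame,
    tree=None,
    seed: int = 0,
    n_permutations: int = 999,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the full comparative analysis and return the validated report.

    ``tree`` may be None, a Newick string, or a dendropy Tree; without a
    tree the phylogenetic stages are skipped with a logged reason.
    Species appearing in several studies are first aggregated to species
    means.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    n_raw = len(table)
    table = aggregate_species_means(table)
    report = AnalysisReport(
        package_version=__version__,
        seed=seed,
        method_notes=[
            "Interaction tests use an OLS ANCOVA F-test in place of a REML "
            "linear mixed model; study enters as a fixed blocking factor "
            "where included.",
            f"Species-mean aggregation: {n_raw} records -> {len(table)} species.",
        ],
    )
    stages = [
        ("anatomy_allometry", lambda: _stage_anatomy(table)),
        ("prs_relationships", lambda: _stage_prs(table)),
        ("nonlinear_trait_fits", lambda: _stage_nonlinear(table)),
    ]
    for name, fn in stages:
        report.stages[name] = fn()
    if tree is None:
        report.stages["phylo"] = StageReport(
            status="skipped", reason="no tree supplied", n_in=len(table), n_out=0
        )
    else:
        report.stages["phylo"] = _stage_phylo(table, tree, n_permutations, seed)
    report.stages["data_source"] = _stage_data_source(table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2))
    return report


# --------------------------------------------------------------------------
# recovery harness


def _fit_group_params(table: pd.DataFrame, form: str) -> dict[str, tuple]:
    sub = table[table["growth_form"] == form].dropna(subset=["diameter", "tToS", "SR"])
    if len(sub) < 3:
        return {}
    t_fit = ols_fit(sub["diameter"], sub["tToS"])
    s_fit = ols_fit(sub["diameter"], sub["SR"])
    return {
        "k": (t_fit.slope, t_fit.slope_se),
        "c": (t_fit.intercept, t_fit.intercept_se),
        "k_sr": (s_fit.slope, s_fit.slope_se),
        "c_sr": (s_fit.intercept, s_fit.intercept_se),
    }


def run_recovery(
    config: GeneratorConfig, n_reps: int = 50, z_crit: float = 1.96
) -> pd.DataFrame:
    """Repeat simulate+fit; summarize bias and 95% CI coverage per truth.

    For every allometry truth parameter of every growth form: the mean
    estimate across replicates, its bias, and the fraction of replicates
    whose Wald interval (estimate ± 1.96 SE) covers the truth.
    """
    if n_reps < 10:
        raise ValueError("need n_reps >= 10")
    from .synthetic import _substream_int

    rows = []
    for rep in range(n_reps):
        rep_config = dataclasses.replace(
            config, seed=_substream_int(config.seed, f"recovery_rep_{rep}")
        )
        table, _, truth = generate_dataset(rep_config)
        for form in ("woody", "non-woody"):
            fits = _fit_group_params(table, form)
            for param, (est, se) in fits.items():
                true_val = truth["groups"][form][param]
                rows.append(
                    {
                        "rep": rep,
                        "growth_form": form,
                        "parameter": param,
                        "estimate": est,
                        "se": se,
                        "truth": true_val,
                        "covered": abs(est - true_val) <= z_crit * se,
                    }
                )
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby(["growth_form", "parameter"])
        .agg(
            truth=("truth", "first"),
            mean_estimate=("estimate", "mean"),
            mean_se=("se", "mean"),
            coverage=("covered", "mean"),
            n_reps=("rep", "nunique"),
        )
        .reset_index()
    )
    summary["bias"] = summary["mean_estimate"] - summary["truth"]
    return summary


def recovery_table(report: AnalysisReport, truth: dict) -> pd.DataFrame:
    """Estimate-vs-truth table for the anatomy allometry stage."""
    rows = []
    stage = report.stages.get("anatomy_allometry")
    if stage is None or stage.status != "ok":
        return pd.DataFrame()
    for form, block in stage.results["by_growth_form"].items():
        if "allometry" not in block:
            continue
        truth_grp = truth["groups"].get(form, {})
        for param, fit_key, field in (
            ("k", "ttos_fit", "slope"),
            ("c", "ttos_fit", "intercept"),
            ("k_sr", "sr_fit", "slope"),
            ("c_sr", "sr_fit", "intercept"),
        ):
            est = block[fit_key][field]
            se = block[fit_key][f"{field}_se"]
            rows.append(
                {
                    "growth_form": form,
                    "parameter": param,
                    "estimate": est,
                    "se": se,
                    "truth": truth_grp.get(param),
                }
            )
    return pd.DataFrame(rows)
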