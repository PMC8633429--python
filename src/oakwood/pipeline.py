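"""Shared readers/writers, input validation and the end-to-end pipeline.

CSV is the single tabular interchange format (Newick for trees); every
output CSV carries a metadata comment header recording package version,
seeds and parameters, so a run is reproducible from its artefacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cooccurrence, phylo, plasticity, traits as traits_mod

log = logging.getLogger("oakwood")

__all__ = [
    "PipelineConfig",
    "read_table",
    "write_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "validate_inputs",
    "run_pipeline",
]

ANATOMICAL_TRAITS = ["VD", "VF", "FD", "FL", "FW", "WD", "H"]
ENV_VARIABLES = ["AI", "mtdq", "pwaq", "pwq", "ps"]

#: plausibility ranges (units as measured) for validation warnings
PLAUSIBLE_RANGES = {
    "VD": (10.0, 500.0),  # um
    "VF": (0.1, 200.0),  # per mm2
    "FL": (1.0, 60.0),  # um
    "FW": (0.5, 20.0),  # um
    "WD": (0.1, 1.4),  # g/cm3
    "H": (1.0, 80.0),  # m
}


@dataclass
class PipelineConfig:
    """Paths, trait list and analysis parameters for one pipeline run."""

    individuals: str
    plots: str
    species: str
    output_dir: str
    tree: str | None = None
    presence: str | None = None
    trait_list: list[str] = field(default_factory=lambda: list(ANATOMICAL_TRAITS))
    env_variables: list[str] = field(default_factory=lambda: list(ENV_VARIABLES))
    log10: bool = True
    vif_threshold: float = 10.0
    n_permutations: int = 5000
    n_randomizations: int = 999
    n_simulations: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate(self):
        for name in ("individuals", "plots", "species", "tree", "presence"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
        if self.seed is None:
            raise ValueError("seed must be set for stochastic pipeline stages")


def _metadata_header(**params) -> str:
    parts = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# oakwood v{__version__} {parts}".rstrip()


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = False, **params):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(**params) + "\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV, skipping metadata comment lines; trait column names are
    upper-cased to the canonical symbols."""
    df = pd.read_csv(path, comment="#", **kwargs)
    rename = {
        c: c.upper() for c in df.columns
        if c.upper() in traits_mod.TRAIT_COLUMNS and c != c.upper()
    }
    return df.rename(columns=rename)


def write_distance_matrix(matrix: plasticity.DistanceMatrix, path: str | Path, **params):
    write_table(matrix.to_frame(), path, index=True, kind=matrix.kind, **params)


def read_distance_matrix(path: str | Path, kind: str = "rdpi") -> plasticity.DistanceMatrix:
    df = pd.read_csv(path, comment="#", index_col=0)
    return plasticity.DistanceMatrix(
        labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float), kind=kind
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationIssue:
    fatal: bool
    message: str


def validate_inputs(
    individuals: pd.DataFrame,
    plots: pd.DataFrame,
    species: pd.DataFrame | None = None,
    tree=None,
    presence: pd.DataFrame | None = None,
) -> list[ValidationIssue]:
    """Schema, name-reconciliation and plausibility checks; returns a report
    (never raises). Fatal issues are flagged."""
    issues: list[ValidationIssue] = []

    def fatal(msg):
        issues.append(ValidationIssue(True, msg))

    def warn(msg):
        issues.append(ValidationIssue(False, msg))

    for col in ("species", "plot"):
        if col not in individuals.columns:
            fatal(f"individual table missing column {col!r}")
            return issues
    if "plot" not in plots.columns:
        fatal("plot table missing column 'plot'")
        return issues

    unknown_plots = set(individuals["plot"]) - set(plots["plot"])
    if unknown_plots:
        fatal(f"plots in individual table missing from plot table: {sorted(unknown_plots)}")
    if "individual" in individuals.columns:
        dup = individuals["individual"][individuals["individual"].duplicated()]
        if len(dup):
            warn(f"duplicated individual ids: {sorted(set(dup))[:5]}")

    for trait, (lo, hi) in PLAUSIBLE_RANGES.items():
        if trait not in individuals.columns:
            continue
        vals = individuals[trait].dropna()
        off = vals[(vals < lo) | (vals > hi)]
        if len(off) > 0.5 * len(vals):
            warn(
                f"{trait}: {len(off)}/{len(vals)} values outside plausible range "
                f"[{lo}, {hi}] — check measurement units"
            )

    if tree is not None:
        tips = {phylo.normalize_name(t) for t in phylo.tip_labels(tree)}
        missing = [
            s for s in individuals["species"].unique()
            if phylo.normalize_name(str(s)) not in tips
        ]
        if missing:
            fatal(f"species present in traits but not in tree: {sorted(missing)}")
    if species is not None and "species" in species.columns:
        unlisted = set(individuals["species"]) - set(species["species"])
        if unlisted:
            warn(f"species without metadata: {sorted(unlisted)}")
    if presence is not None:
        empty = presence.index[(presence == 0).all(axis=1)].tolist()
        if empty:
            warn(f"species with all-zero presence rows: {empty}")
    return issues


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write one CSV per result plus a manifest.

    Stages: derived variables -> species means -> {correlations + PCA,
    RDPI -> distance matrices -> MRM, co-occurrence, Blomberg's K + PGLS +
    phylogenetic ANOVA}. When no tree is configured the phylogenetic stages
    are skipped with a logged notice and the rest completes.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    meta = {"seed": config.seed, "log10": config.log10}

    indiv = read_table(config.individuals)
    plots = read_table(config.plots)
    species_meta = read_table(config.species)
    tree = None
    if config.tree:
        tree = phylo.read_newick(Path(config.tree).read_text())
    presence = None
    if config.presence:
        presence = pd.read_csv(config.presence, comment="#", index_col=0)

    issues = validate_inputs(indiv, plots, species_meta, tree, presence)
    for issue in issues:
        (log.error if issue.fatal else log.warning)("validate: %s", issue.message)
    if any(i.fatal for i in issues):
        raise ValueError("fatal validation issues; aborting: "
                         + "; ".join(i.message for i in issues if i.fatal))

    stage = "derive"
    try:
        derived = traits_mod.derive_vessel_variables(
            indiv["VD"], indiv["VF"], indiv["VA"] if "VA" in indiv else None
        )
        indiv = indiv.assign(S=derived.S, F=derived.F, VI=derived.VI, RC=derived.RC)
        if "FD" not in indiv.columns and {"FL", "FW"} <= set(indiv.columns):
            indiv["FD"] = traits_mod.fibre_total_diameter(indiv["FL"], indiv["FW"])
        write_table(indiv, out / "individuals_derived.csv", **meta)

        stage = "species_means"
        all_traits = config.trait_list + [
            c for c in traits_mod.DERIVED_COLUMNS if c in indiv.columns
        ]
        means = traits_mod.species_means(indiv, log10=config.log10, columns=all_traits)
        write_table(means, out / "species_means.csv", index=True, **meta)
        results["species_means"] = means

        stage = "environment"
        env = plots[[v for v in config.env_variables if v in plots.columns]]
        vif = traits_mod.select_variables_vif(env, threshold=config.vif_threshold)
        results["vif"] = vif
        write_table(
            pd.DataFrame({"variable": vif.retained,
                          "vif": [vif.vif[v] for v in vif.retained]}),
            out / "vif_retained.csv", removed=",".join(vif.removed) or "none", **meta,
        )

        stage = "rdpi"
        rdpi_tab = plasticity.rdpi_table(indiv, all_traits)
        write_table(rdpi_tab, out / "rdpi.csv",
                    excluded=",".join(rdpi_tab.attrs["excluded"]) or "none", **meta)
        results["rdpi"] = rdpi_tab

        stage = "mrm"
        geo = plasticity.geographic_distance(plots)
        envd = plasticity.environmental_distance(plots, vif.retained)
        write_distance_matrix(geo, out / "distance_geographic.csv", **meta)
        write_distance_matrix(envd, out / "distance_environmental.csv", **meta)
        section_map = species_meta.set_index("species")["section"]
        mrm_rows = []
        plot_order = [str(p) for p in plots["plot"]]
        for section in sorted(section_map.unique()):
            sect_species = [
                s for s in section_map.index[section_map == section]
                if (indiv["species"] == s).any()
                and indiv.loc[indiv["species"] == s, "plot"].nunique() >= 2
            ]
            for trait in config.trait_list:
                mats = [
                    plasticity.rdpi_plot_pair_matrix(indiv, s, trait, plots=plot_order)
                    for s in sect_species
                ]
                if not mats:
                    continue
                avg = plasticity.section_mean(mats)
                transformed = plasticity.DistanceMatrix(
                    avg.labels, plasticity.rdpi_transform(avg.values), kind="rdpi"
                )
                try:
                    fit = plasticity.mrm(
                        transformed, [geo, envd],
                        n_permutations=config.n_permutations, seed=config.seed,
                    )
                except ValueError as exc:
                    log.warning("mrm %s/%s skipped: %s", section, trait, exc)
                    continue
                mrm_rows.append(
                    {"section": section, "trait": trait, "r_squared": fit.r_squared,
                     "p_r_squared": fit.p_r_squared,
                     "coef_geographic": fit.coefficients[1],
                     "p_geographic": fit.p_coefficients[0],
                     "coef_environmental": fit.coefficients[2],
                     "p_environmental": fit.p_coefficients[1],
                     "n_pairs": fit.n_pairs_used}
                )
        mrm_table = pd.DataFrame(mrm_rows)
        write_table(mrm_table, out / "mrm.csv",
                    permutations=config.n_permutations, **meta)
        results["mrm"] = mrm_table

        stage = "cooccurrence"
        if presence is not None:
            pairs, summary = cooccurrence.cooccurrence_table(presence, alpha=config.alpha)
            write_table(pairs, out / "cooccurrence_pairs.csv", alpha=config.alpha, **meta)
            results["cooccurrence"] = (pairs, summary)

        if tree is not None:
            stage = "phylogenetic"
            mapping = phylo.reconcile_names(tree, means.index)
            ptree = phylo.prune(tree, [mapping[s] for s in means.index])
            pmeans = means.rename(index=mapping)
            corr = phylo.combined_correlation_table(pmeans, ptree)
            write_table(corr, out / "correlations_raw_below_pic_above.csv",
                        index=True, **meta)
            results["correlations"] = corr

            pca_traits = phylo.pca(pmeans, standardize=True,
                                   exclude=[c for c in ("VA", "S") if c in pmeans])
            results["pca"] = pca_traits
            write_table(pca_traits.loadings, out / "pca_loadings.csv", index=True,
                        pct=",".join(f"{v:.2f}" for v in pca_traits.percent_variance[:3]),
                        **meta)

            signal_rows = []
            for trait in pmeans.columns:
                sig = phylo.blomberg_k(
                    ptree, pmeans[trait],
                    n_randomizations=config.n_randomizations, seed=config.seed,
                )
                signal_rows.append({"trait": trait, "K": sig.K, "p": sig.p_value})
            signal = pd.DataFrame(signal_rows)
            write_table(signal, out / "blomberg_k.csv",
                        randomizations=config.n_randomizations, **meta)
            results["signal"] = signal

            env_plot = plots.set_index("plot")
            exposure = {
                v: indiv.groupby("species")["plot"].apply(
                    lambda s, v=v: env_plot.loc[s, v].mean()
                ).rename(index=mapping)
                for v in vif.retained
            }
            pgls_rows = []
            for trait in config.trait_list:
                best = phylo.model_select(ptree, pmeans[trait], pd.DataFrame(exposure))
                pgls_rows.append(
                    {"trait": trait, "best_predictor": best.predictor,
                     "slope": best.coefficients[1], "p": best.p_values[1],
                     "aic": best.aic}
                )
            write_table(pd.DataFrame(pgls_rows), out / "pgls_best_models.csv", **meta)
            results["pgls"] = pd.DataFrame(pgls_rows)

            groups = species_meta.set_index("species")["section"].rename(index=mapping)
            anova_rows = []
            for trait in config.trait_list:
                try:
                    res = phylo.phyl_anova(
                        ptree, pmeans[trait], groups,
                        n_simulations=config.n_simulations, seed=config.seed,
                    )
                    anova_rows.append({"trait": trait, "F": res.F, "p": res.p_value})
                except ValueError as exc:
                    log.warning("phyl_anova %s skipped: %s", trait, exc)
            write_table(pd.DataFrame(anova_rows), out / "phyl_anova.csv",
                        simulations=config.n_simulations, **meta)
            results["phyl_anova"] = pd.DataFrame(anova_rows)
        else:
            log.info("no tree configured; skipping phylogenetic stages")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "log10": config.log10, "vif_threshold": config.vif_threshold,
            "n_permutations": config.n_permutations,
            "n_randomizations": config.n_randomizations,
            "n_simulations": config.n_simulations, "alpha": config.alpha,
        },
        "inputs": {
            name: {"path": str(p), "sha256_16": _checksum(p)}
            for name, p in (
                ("individuals", config.individuals), ("plots", config.plots),
                ("species", config.species), ("tree", config.tree),
                ("presence", config.presence),
            )
            if p
        },
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
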