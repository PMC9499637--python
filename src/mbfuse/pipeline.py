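"""End-to-end orchestration: simulate/load -> normalize -> ecology ->
clinical -> univariate -> fusion/rDCV, with a reproducible manifest.

Every stage writes its outputs as TSV/JSON under the output directory and
registers them in a manifest (parameters, seed, package version, SHA-256
content hashes, per-stage wall time), so a rerun with the same config and
seed is verifiably content-identical and any silent input change is
detectable.  Stage failures abort with the stage name and offending input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import pca_autoscaled
from .ecology import (alpha_diversity_table, bray_curtis, intragroup_distances,
                      pcoa, permanova)
from .feature_table import (FeatureTable, css_normalize, css_reference_quantile,
                            filter_features, read_table, read_taxonomy,
                            relative_abundance)
from .fusion import (RDCVConfig, RDCVResult, confirm_features, permutation_test,
                     rdcv, select_features_vip)
from .synthetic_data import (SimulationParams, default_study_params,
                             generate_study, write_bundle)
from .univariate import (ANTI_GAD_SCHEME, PH_BINARY, PH_STRATA, IntervalScheme,
                         ThresholdScheme, differential_features, kruskal_wallis,
                         pearson_matrix, stratify_samples)

log = logging.getLogger(__name__)

SCHEMES: dict[str, IntervalScheme | ThresholdScheme] = {
    "ph_strata": PH_STRATA,
    "ph_binary": PH_BINARY,
    "anti_gad": ANTI_GAD_SCHEME,
}

#: clinical variables entering the unsupervised PCA
CLINICAL_PCA_VARIABLES = ("anti_GAD", "IAA", "IA2", "HbA1c", "cholesterol",
                          "insulin_need", "blood_pH", "age", "c_peptide")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ContrastSide:
    """One side of a two-class contrast: a group label, optionally narrowed
    to a stratum of the configured clinical stratification."""

    group: str | None = None
    stratum: str | None = None

    @property
    def name(self) -> str:
        if self.stratum is not None:
            return self.stratum if self.group is None else f"{self.group}:{self.stratum}"
        return str(self.group)


@dataclass
class Contrast:
    name: str
    a: ContrastSide
    b: ContrastSide


def default_contrasts() -> list[Contrast]:
    """The four study contrasts: patients vs controls, and the blood-pH
    severity strata against controls and each other."""
    return [
        Contrast("T1D_vs_CTRL", ContrastSide("T1D"), ContrastSide("CTRL")),
        Contrast("pHlow_vs_CTRL", ContrastSide("T1D", "pH<7.32"), ContrastSide("CTRL")),
        Contrast("pHhigh_vs_CTRL", ContrastSide("T1D", "pH>=7.32"), ContrastSide("CTRL")),
        Contrast("pHhigh_vs_pHlow", ContrastSide("T1D", "pH>=7.32"),
                 ContrastSide("T1D", "pH<7.32")),
    ]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)   # SimulationParams overrides
    inputs: dict = field(default_factory=dict)       # counts/metabolites/clinical/taxonomy paths
    group_column: str = "group"
    min_total_fraction: float = 0.01
    min_prevalence: float = 0.25
    css_quantile: float | None = None                # None -> adaptive
    css_scale: float = 1000.0
    alpha_metrics: tuple = ("shannon", "simpson", "chao1")
    shannon_base: float = 2.0
    permanova_permutations: int = 999
    univariate_alpha: float = 0.05
    univariate_alpha_adjusted: float = 0.1
    stratification_variable: str = "blood_pH"
    stratification_scheme: str = "ph_binary"
    stratification_group: str = "T1D"
    pca_group: str = "T1D"
    contrasts: list = field(default_factory=default_contrasts)
    rdcv: RDCVConfig = field(default_factory=RDCVConfig)
    permutation_enabled: bool = False
    permutation_n: int = 99
    permutation_null_repeats: int = 1
    vip_confirm_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "contrasts" in d:
            d["contrasts"] = [
                Contrast(c["name"], ContrastSide(**c["a"]), ContrastSide(**c["b"]))
                for c in d["contrasts"]]
        if "rdcv" in d:
            d["rdcv"] = RDCVConfig(**d["rdcv"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [{"name": c.name,
                           "a": dataclasses.asdict(c.a),
                           "b": dataclasses.asdict(c.b)}
                          for c in self.contrasts]
        return d


def simulation_params(config: PipelineConfig) -> SimulationParams:
    """Materialize SimulationParams from the config's overrides + seed."""
    params = default_study_params(seed=config.seed)
    overrides = dict(config.simulation)
    if overrides.pop("no_planted_effects", False):
        params = replace(params, planted_taxa=(), planted_metabolites=(), links=())
    if "group_sizes" in overrides:
        overrides["group_sizes"] = {str(k): int(v)
                                    for k, v in overrides["group_sizes"].items()}
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    return replace(params, **overrides)


# ---------------------------------------------------------------------------
# contrast resolution
# ---------------------------------------------------------------------------

def resolve_contrast(groups: pd.Series, strata: pd.Series,
                     contrast: Contrast) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices and two-class labels for a contrast.

    ``groups`` maps sample -> group label; ``strata`` maps sample ->
    stratum (may omit samples).  Returns (positions, labels) where labels
    take the side names and side ``a`` is the positive class.
    """
    def side_mask(side: ContrastSide) -> pd.Series:
        mask = pd.Series(True, index=groups.index)
        if side.group is not None:
            mask &= groups == side.group
        if side.stratum is not None:
            mask &= groups.index.isin(strata.index[strata == side.stratum])
        return mask

    ma, mb = side_mask(contrast.a), side_mask(contrast.b)
    overlap = ma & mb
    if overlap.any():
        raise ValueError(f"contrast {contrast.name!r}: sides overlap "
                         f"({int(overlap.sum())} samples)")
    for side, m in ((contrast.a, ma), (contrast.b, mb)):
        if not m.any():
            raise ValueError(f"contrast {contrast.name!r}: side {side.name!r} "
                             "selects no samples")
    labels = pd.Series(pd.NA, index=groups.index, dtype=object)
    labels[ma] = contrast.a.name
    labels[mb] = contrast.b.name
    keep = labels.notna().to_numpy()
    return np.flatnonzero(keep), labels.to_numpy()[keep].astype(str)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.doc = {"package": "mbfuse", "version": __version__,
                    "seed": config.seed, "config": config.to_dict(),
                    "outputs": {}, "timings_s": {}}

    def register(self, path: Path) -> None:
        self.doc["outputs"][str(path.relative_to(self.outdir))] = _sha256(path)

    def time_stage(self, stage: str, seconds: float) -> None:
        self.doc["timings_s"][stage] = round(seconds, 3)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))
        return path


def _derived_seed(base: int, *salt: int) -> int:
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0] % (2 ** 31))


def _chemometric_blocks(metabolites: FeatureTable, css_counts: FeatureTable,
                        positions: np.ndarray) -> dict[str, pd.DataFrame]:
    """Metabolite concentrations and log1p CSS taxa abundances as named
    blocks (DataFrames, so VIP reports carry real feature IDs)."""
    return {
        "metabolites": metabolites.data.iloc[positions],
        "taxa": np.log1p(css_counts.data.iloc[positions]),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in order; returns the manifest document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                manifest.time_stage(name, time.perf_counter() - self_inner.t0)
                log.info("stage %s: done", name)
        return _Timer()

    # ---- stage: data -----------------------------------------------------
    with stage("data"):
        if config.simulate:
            params = simulation_params(config)
            bundle = generate_study(params)
            paths = write_bundle(bundle, outdir / "simulated")
            for p in paths.values():
                manifest.register(p)
            counts, metabolites = bundle.counts, bundle.metabolites
            clinical, taxonomy = bundle.clinical, bundle.taxonomy
        else:
            req = {"counts", "metabolites", "clinical"}
            missing = req - set(config.inputs)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")
            counts = read_table(config.inputs["counts"])
            metabolites = read_table(config.inputs["metabolites"])
            clinical = pd.read_csv(config.inputs["clinical"], sep="\t", index_col=0)
            taxonomy = (read_taxonomy(config.inputs["taxonomy"])
                        if "taxonomy" in config.inputs else None)
        if config.group_column not in clinical.columns:
            raise ValueError(
                f"metadata column {config.group_column!r} not found in clinical table")
        groups = clinical[config.group_column].astype(str)

    # ---- stage: normalize ------------------------------------------------
    with stage("normalize"):
        filtered, removed = filter_features(counts, config.min_total_fraction,
                                            config.min_prevalence)
        quantile = (config.css_quantile if config.css_quantile is not None
                    else css_reference_quantile(filtered))
        css_counts = css_normalize(filtered, quantile, config.css_scale)
        rel = relative_abundance(filtered)
        filtered.to_tsv(outdir / "filtered_counts.tsv")
        css_counts.to_tsv(outdir / "css_counts.tsv")
        removed.to_csv(outdir / "removed_features.tsv", sep="\t", index=False)
        for f in ("filtered_counts.tsv", "css_counts.tsv", "removed_features.tsv"):
            manifest.register(outdir / f)
        manifest.doc["css_quantile"] = quantile

    # ---- stage: ecology --------------------------------------------------
    with stage("ecology"):
        alpha = alpha_diversity_table(filtered, config.alpha_metrics,
                                      base=config.shannon_base)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id")
        alpha_tests = {m: dict(zip(("H", "p"),
                                   kruskal_wallis(alpha[m], groups.to_numpy())))
                       for m in alpha.columns}
        dm = bray_curtis(css_counts)
        dm.to_tsv(outdir / "bray_curtis.tsv")
        ord_res = pcoa(dm, k=2)
        ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t",
                                   index_label="sample_id")
        perm = permanova(dm, groups.to_numpy(), config.permanova_permutations,
                         seed=_derived_seed(config.seed, 1))
        intra = intragroup_distances(dm, groups.to_numpy())
        eco = {
            "alpha_kruskal_wallis": alpha_tests,
            "pcoa_eigenvalues": ord_res.eigenvalues.tolist(),
            "pcoa_proportions": ord_res.proportions.tolist(),
            "permanova": {"pseudo_F": perm.pseudo_f, "p": perm.p_value,
                          "n_permutations": perm.n_permutations,
                          "exhaustive": perm.exhaustive},
            "intragroup": {"median_distance":
                           {g: float(np.median(v))
                            for g, v in intra.distances.items()},
                           "kruskal_wallis": {"H": intra.kw_statistic,
                                              "p": intra.kw_p_value}},
        }
        (outdir / "ecology.json").write_text(json.dumps(eco, indent=2))
        for f in ("alpha_diversity.tsv", "bray_curtis.tsv",
                  "pcoa_coordinates.tsv", "ecology.json"):
            manifest.register(outdir / f)

    # ---- stage: clinical -------------------------------------------------
    with stage("clinical"):
        missing_vars = [v for v in CLINICAL_PCA_VARIABLES
                        if v not in clinical.columns]
        if missing_vars:
            raise ValueError(f"clinical table lacks variables: {missing_vars}")
        sub = clinical.loc[groups == config.pca_group,
                           list(CLINICAL_PCA_VARIABLES)]
        n_dropped = int(sub.isna().any(axis=1).sum())
        if n_dropped:
            log.info("clinical PCA: dropped %d rows with missing values", n_dropped)
        sub = sub.dropna()
        model = pca_autoscaled(sub.to_numpy(), k=min(3, len(sub) - 1))
        rmat, pmat = pearson_matrix(sub)
        rmat.to_csv(outdir / "clinical_correlations_r.tsv", sep="\t")
        pmat.to_csv(outdir / "clinical_correlations_p.tsv", sep="\t")
        scheme = SCHEMES[config.stratification_scheme]
        strat_rows = clinical.loc[groups == config.stratification_group]
        strata = stratify_samples(strat_rows, config.stratification_variable, scheme)
        strata.to_frame().to_csv(outdir / "strata.tsv", sep="\t",
                                 index_label="sample_id")
        clin = {
            "pca_variance_fractions": model.variance_fractions.tolist(),
            "pca_loadings": {v: model.loadings[i].tolist()
                             for i, v in enumerate(CLINICAL_PCA_VARIABLES)},
            "n_rows_used": int(len(sub)),
            "n_rows_dropped_missing": n_dropped,
            "strata_counts": strata.value_counts().to_dict(),
        }
        (outdir / "clinical.json").write_text(json.dumps(clin, indent=2))
        for f in ("clinical_correlations_r.tsv", "clinical_correlations_p.tsv",
                  "strata.tsv", "clinical.json"):
            manifest.register(outdir / f)

    # ---- stage: univariate -----------------------------------------------
    with stage("univariate"):
        diff_taxa = differential_features(
            rel, groups.to_numpy(), test="kruskal", adjust="bh_fdr",
            alpha=config.univariate_alpha,
            alpha_adjusted=config.univariate_alpha_adjusted)
        diff_mets = differential_features(
            metabolites, groups.to_numpy(), test="kruskal", adjust="bh_fdr",
            alpha=config.univariate_alpha,
            alpha_adjusted=config.univariate_alpha_adjusted)
        diff_taxa.to_csv(outdir / "differential_taxa.tsv", sep="\t", index=False)
        diff_mets.to_csv(outdir / "differential_metabolites.tsv", sep="\t",
                         index=False)
        manifest.register(outdir / "differential_taxa.tsv")
        manifest.register(outdir / "differential_metabolites.tsv")

    # ---- stage: fusion ---------------------------------------------------
    with stage("fusion"):
        results = compare_contrasts(metabolites, css_counts, groups, strata,
                                    config)
        summary = {}
        for ci, (cname, models) in enumerate(results.items()):
            cdir = outdir / "contrasts" / cname
            cdir.mkdir(parents=True, exist_ok=True)
            summary[cname] = {}
            for mname, res in models.items():
                res.to_json(cdir / f"rdcv_{mname}.json")
                manifest.register(cdir / f"rdcv_{mname}.json")
                summary[cname][mname] = res.summary()
            fused = models["fused"]
            selection = select_features_vip(fused)
            selection.to_csv(cdir / "vip_selection.tsv", sep="\t", index=False)
            manifest.register(cdir / "vip_selection.tsv")
            contrast = _contrast_by_name(config, cname)
            pos_idx, labels = resolve_contrast(groups, strata, contrast)
            blocks = _chemometric_blocks(metabolites, css_counts, pos_idx)
            confirmed = confirm_features(blocks, labels, selection,
                                         alpha=config.vip_confirm_alpha)
            confirmed.to_csv(cdir / "vip_confirmed.tsv", sep="\t", index=False)
            manifest.register(cdir / "vip_confirmed.tsv")
            if config.permutation_enabled:
                cfg = replace(config.rdcv, seed=_derived_seed(config.seed, 2, ci))
                pr = permutation_test(blocks, labels, cfg,
                                      n_perm=config.permutation_n,
                                      null_repeats=config.permutation_null_repeats,
                                      positive=contrast.a.name)
                (cdir / "permutation.json").write_text(json.dumps(
                    {"observed": pr.observed, "p_values": pr.p_values,
                     "n_permutations": pr.n_permutations}, indent=2))
                manifest.register(cdir / "permutation.json")
        (outdir / "fusion_summary.json").write_text(json.dumps(summary, indent=2))
        manifest.register(outdir / "fusion_summary.json")

    path = manifest.write()
    log.info("pipeline complete; manifest at %s", path)
    return manifest.doc


def _contrast_by_name(config: PipelineConfig, name: str) -> Contrast:
    for c in config.contrasts:
        if c.name == name:
            return c
    raise KeyError(name)


def compare_contrasts(metabolites: FeatureTable, css_counts: FeatureTable,
                      groups: pd.Series, strata: pd.Series,
                      config: PipelineConfig) -> dict[str, dict[str, RDCVResult]]:
    """Single-block and fused rDCV models for every configured contrast.

    For each contrast three models are validated: metabolites only, taxa
    only (log1p CSS abundances), and the Frobenius-fused multi-block model.
    Returns contrast name -> model name -> :class:`RDCVResult`.
    """
    out: dict[str, dict[str, RDCVResult]] = {}
    for i, contrast in enumerate(config.contrasts):
        positions, labels = resolve_contrast(groups, strata, contrast)
        blocks = _chemometric_blocks(metabolites, css_counts, positions)
        out[contrast.name] = {}
        for j, (mname, X) in enumerate((
                ("metabolites", blocks["metabolites"]),
                ("taxa", blocks["taxa"]),
                ("fused", blocks))):
            cfg = replace(config.rdcv, seed=_derived_seed(config.rdcv.seed, i, j))
            out[contrast.name][mname] = rdcv(X, labels, cfg,
                                             positive=contrast.a.name)
    return out
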