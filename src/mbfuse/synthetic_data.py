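"""Synthetic paired microbiome / metabolome / clinical study generator.

Emulates the statistical design of a three-group pediatric type-1-diabetes
(T1D) onset study — T1D patients, their siblings and healthy controls
(default 52/17/57 subjects) — so the whole analysis pipeline can be
exercised and validated without any sequence download:

* 16S count tables: per-sample library sizes are log-normal (mean 75,154
  reads by default), compositions are Dirichlet-multinomial around a
  group-specific composition obtained by applying planted log2 fold
  changes to a common baseline (Dirichlet-multinomial rather than plain
  multinomial, to give the overdispersion real 16S tables show);
* metabolite tables: log-normal concentrations (µmol/g feces semantics)
  with planted standardized group mean shifts on the log scale and,
  optionally, planted taxon-metabolite correlations realized as a linear
  blend of the linked taxon's CSS-normalized log abundance and
  independent noise (blend weight = target Pearson r);
* clinical tables: a Gaussian copula reproduces a target pairwise
  correlation matrix among nine clinical variables (anti-GAD, IAA, IA-2,
  HbA1c, cholesterol, insulin need, blood pH, age, c-peptide); latent
  correlations are calibrated by quadrature so the *output* Pearson
  correlations hit the targets despite non-normal marginals.  Blood pH is
  drawn from a two-component mixture straddling 7.32, mirroring the
  ketoacidosis severity strata of such cohorts.

A single global seed expands into independent per-table substreams, so
adding or regenerating one table never perturbs the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm

from .feature_table import FeatureTable, css_normalize

log = logging.getLogger(__name__)

DEFAULT_GROUP_SIZES = {"T1D": 52, "sibling": 17, "CTRL": 57}

#: 37 metabolites of the classes quantified by 1H-NMR on feces
DEFAULT_METABOLITES = (
    "butyrate", "isobutyrate", "malonate", "succinate", "ethanol",
    "galactose", "uracil", "formate", "fumarate", "hypoxanthine",
    "guanine", "isovalerate", "propionate", "acetate", "lactate",
    "2-methylbutyrate", "2-aminoisobutyrate", "dimethylamine",
    "trimethylamine", "methanol", "glucose", "xylose", "ribose",
    "alanine", "glycine", "glutamate", "valine", "leucine", "isoleucine",
    "threonine", "lysine", "tyrosine", "phenylalanine", "methionine",
    "aspartate", "malate", "citrate",
)

#: (phylum, family, genus) pool used to build a synthetic taxonomy; the
#: first entries line up with the taxa planted by default_study_params
_TAXON_POOL = (
    ("Firmicutes", "Clostridiaceae", "Clostridium"),
    ("Firmicutes", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Veillonellaceae", "Dialister"),
    ("Verrucomicrobia", "Verrucomicrobiaceae", "Akkermansia"),
    ("Actinobacteria", "Coriobacteriaceae", "Collinsella"),
    ("Firmicutes", "Lachnospiraceae", "Dorea"),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Bacteroidetes", "Rikenellaceae", "Alistipes"),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Lachnospiraceae", "Roseburia"),
    ("Bacteroidetes", "Odoribacteraceae", "Odoribacter"),
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Porphyromonadaceae", "Parabacteroides"),
    ("Proteobacteria", "Sutterellaceae", "Sutterella"),
    ("Firmicutes", "Turicibacteraceae", "Turicibacter"),
    ("Actinobacteria", "Actinomycetaceae", "Actinomyces"),
    ("Actinobacteria", "Coriobacteriaceae", "Eggerthella"),
    ("Firmicutes", "Ruminococcaceae", "Oscillospira"),
    ("Firmicutes", "Christensenellaceae", "Christensenella"),
    ("Firmicutes", "Erysipelotrichaceae", "Catenibacterium"),
)


# ---------------------------------------------------------------------------
# marginal distributions & the Gaussian copula
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one clinical variable.

    ``kind`` is ``"normal"`` (params: mean, sd), ``"lognormal"`` (params:
    mean, sd of the variable itself — converted to log-scale mu/sigma), or
    ``"mixture"`` of normals (params: components = ((weight, mean, sd), ...)).
    ``clip`` optionally bounds the support (e.g. non-negative concentrations);
    clipping is part of the transform, so copula calibration accounts for it.
    """

    kind: str
    params: tuple = ()
    clip: tuple[float | None, float | None] | None = None

    def transform(self) -> Callable[[np.ndarray], np.ndarray]:
        """Map a standard normal draw z to the marginal, monotonically."""
        if self.kind == "normal":
            mean, sd = self.params
            base = lambda z: mean + sd * z
        elif self.kind == "lognormal":
            mean, sd = self.params
            if mean <= 0:
                raise ValueError("lognormal mean must be positive")
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            sigma = np.sqrt(sigma2)
            base = lambda z: np.exp(mu + sigma * z)
        elif self.kind == "mixture":
            comps = self.params
            w = np.array([c[0] for c in comps], dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")
            mus = np.array([c[1] for c in comps], dtype=float)
            sds = np.array([c[2] for c in comps], dtype=float)
            lo = (mus - 8 * sds).min()
            hi = (mus + 8 * sds).max()
            grid = np.linspace(lo, hi, 4001)
            cdf = sum(wi * norm.cdf((grid - m) / s) for wi, m, s in zip(w, mus, sds))
            cdf = np.clip(cdf, 0.0, 1.0)
            base = lambda z: np.interp(norm.cdf(z), cdf, grid)
        else:
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.clip is None:
            return base
        lo, hi = self.clip
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        return lambda z: np.clip(base(z), lo, hi)


@dataclass
class ClinicalSpec:
    """Marginals plus a target pairwise Pearson correlation structure."""

    marginals: dict[str, Marginal]
    correlations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.marginals)

    def target_matrix(self) -> pd.DataFrame:
        names = self.variables
        R = np.eye(len(names))
        ix = {v: i for i, v in enumerate(names)}
        for a, b, r in self.correlations:
            if a not in ix or b not in ix:
                raise ValueError(f"correlation references unknown variable ({a}, {b})")
            if abs(r) > 1:
                raise ValueError(f"|target r| must be <= 1, got {r}")
            R[ix[a], ix[b]] = R[ix[b], ix[a]] = r
        return pd.DataFrame(R, index=names, columns=names)

    def validate(self) -> None:
        R = self.target_matrix().to_numpy()
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin < -1e-8:
            raise ValueError(
                f"target correlation matrix is not positive semidefinite "
                f"(min eigenvalue {eigmin:.3g})")


_GH_NODES, _GH_WEIGHTS = hermegauss(41)  # E[f(Z)] = sum w_i f(x_i) / sqrt(2*pi)
_GH_W = _GH_WEIGHTS / np.sqrt(2 * np.pi)


def _marginal_moments(T: Callable) -> tuple[float, float]:
    vals = T(_GH_NODES)
    m = float(_GH_W @ vals)
    v = float(_GH_W @ (vals - m) ** 2)
    return m, np.sqrt(v)


def _pearson_given_latent(T1: Callable, T2: Callable, rho: float,
                          m1, s1, m2, s2) -> float:
    z1 = _GH_NODES[:, None]
    z2 = rho * _GH_NODES[:, None] + np.sqrt(max(0.0, 1 - rho ** 2)) * _GH_NODES[None, :]
    vals = (T1(z1) - m1) * (T2(z2) - m2)
    e = float(_GH_W @ vals @ _GH_W)
    return e / (s1 * s2)


def _calibrate_latent_rho(T1: Callable, T2: Callable, target: float) -> float:
    """Find the latent normal correlation giving the target output Pearson r.

    The map latent rho -> output Pearson is continuous and non-decreasing
    for monotone transforms, so bisection applies.  Targets beyond the
    attainable range (possible for very skewed marginals) are clamped to
    the boundary with a warning.
    """
    if target == 0:
        return 0.0
    m1, s1 = _marginal_moments(T1)
    m2, s2 = _marginal_moments(T2)
    lo, hi = -0.9999, 0.9999
    flo = _pearson_given_latent(T1, T2, lo, m1, s1, m2, s2)
    fhi = _pearson_given_latent(T1, T2, hi, m1, s1, m2, s2)
    if target <= flo:
        log.warning("target r=%.3f below attainable range [%.3f, %.3f]; clamped",
                    target, flo, fhi)
        return lo
    if target >= fhi:
        log.warning("target r=%.3f above attainable range [%.3f, %.3f]; clamped",
                    target, flo, fhi)
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if _pearson_given_latent(T1, T2, mid, m1, s1, m2, s2) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipping repair, renormalized to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 1e-10:
        return R
    vals = np.clip(vals, 1e-10, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def default_clinical_spec() -> ClinicalSpec:
    """Nine clinical variables with cohort-realistic marginals.

    Means/SDs follow typical values reported for pediatric T1D onset
    cohorts; blood pH is a two-component mixture straddling the 7.32
    severity cut-off (components 7.38 ± 0.04 and 7.18 ± 0.08, weights
    0.46/0.54, mirroring the observed strata proportions).  Planted
    correlations: insulin need with HbA1c (+0.33) and blood pH (−0.33),
    anti-GAD with HbA1c (−0.36).
    """
    marginals = {
        "anti_GAD": Marginal("lognormal", (31.80, 40.91)),
        "IAA": Marginal("normal", (6.38, 3.56), clip=(0.0, None)),
        "IA2": Marginal("lognormal", (40.56, 208.44)),
        "HbA1c": Marginal("normal", (102.37, 22.71), clip=(0.0, None)),
        "cholesterol": Marginal("normal", (155.65, 49.87), clip=(0.0, None)),
        "insulin_need": Marginal("normal", (0.84, 0.25), clip=(0.0, None)),
        "blood_pH": Marginal("mixture", ((0.46, 7.38, 0.04), (0.54, 7.18, 0.08))),
        "age": Marginal("normal", (9.52, 3.21), clip=(1.0, 18.0)),
        "c_peptide": Marginal("normal", (0.31, 0.19), clip=(0.0, None)),
    }
    correlations = [
        ("insulin_need", "HbA1c", 0.33),
        ("insulin_need", "blood_pH", -0.33),
        ("anti_GAD", "HbA1c", -0.36),
    ]
    return ClinicalSpec(marginals, correlations)


# ---------------------------------------------------------------------------
# simulation parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTaxon:
    """Taxon index with per-group log2 fold changes vs the baseline."""
    index: int
    log2_fold_change: tuple[tuple[str, float], ...]

    def fc(self, group: str) -> float:
        return dict(self.log2_fold_change).get(group, 0.0)


@dataclass(frozen=True)
class PlantedMetabolite:
    """Metabolite index with per-group standardized (log-scale) mean shifts."""
    index: int
    shift: tuple[tuple[str, float], ...]

    def delta(self, group: str) -> float:
        return dict(self.shift).get(group, 0.0)


@dataclass(frozen=True)
class TaxonMetaboliteLink:
    """Planted Pearson correlation between a taxon and a metabolite."""
    taxon: int
    metabolite: int
    r: float


@dataclass
class SimulationParams:
    """Full specification of one synthetic study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_taxa: int = 150
    n_metabolites: int = 37
    library_size_mean: float = 75154.0
    library_size_cv: float = 0.3
    baseline_concentration: float = 200.0
    planted_taxa: tuple[PlantedTaxon, ...] = ()
    planted_metabolites: tuple[PlantedMetabolite, ...] = ()
    links: tuple[TaxonMetaboliteLink, ...] = ()
    clinical: ClinicalSpec = field(default_factory=default_clinical_spec)
    metabolite_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("at least one group is required")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} size must be >= 2, got {n}")
        if self.n_taxa < 1 or self.n_metabolites < 1:
            raise ValueError("n_taxa and n_metabolites must be positive")
        if self.library_size_mean <= 0 or self.library_size_cv <= 0:
            raise ValueError("library size mean and CV must be positive")
        if self.baseline_concentration <= 0:
            raise ValueError("baseline_concentration must be positive")
        for pt in self.planted_taxa:
            if not 0 <= pt.index < self.n_taxa:
                raise ValueError(f"planted taxon index {pt.index} out of range")
            for _, fc in pt.log2_fold_change:
                if not np.isfinite(fc):
                    raise ValueError("fold changes must be finite")
        for pm in self.planted_metabolites:
            if not 0 <= pm.index < self.n_metabolites:
                raise ValueError(f"planted metabolite index {pm.index} out of range")
        met_linked = set()
        for lk in self.links:
            if not 0 <= lk.taxon < self.n_taxa:
                raise ValueError(f"link references missing taxon {lk.taxon}")
            if not 0 <= lk.metabolite < self.n_metabolites:
                raise ValueError(f"link references missing metabolite {lk.metabolite}")
            if abs(lk.r) > 1:
                raise ValueError(f"|target r| must be <= 1, got {lk.r}")
            if lk.metabolite in met_linked:
                raise ValueError(f"metabolite {lk.metabolite} linked more than once")
            met_linked.add(lk.metabolite)
        self.clinical.validate()

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


def _substreams(params: SimulationParams) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(params.seed).spawn(3)
    return {"counts": children[0], "metabolites": children[1],
            "clinical": children[2]}


def _sample_index(params: SimulationParams) -> tuple[list[str], np.ndarray]:
    ids, groups = [], []
    for g, n in params.group_sizes.items():
        for i in range(n):
            ids.append(f"{g}_{i + 1:03d}")
            groups.append(g)
    return ids, np.array(groups)


def group_labels(params: SimulationParams) -> np.ndarray:
    """Group label per sample, in the bundle's fixed sample order."""
    return _sample_index(params)[1]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_counts(params: SimulationParams) -> FeatureTable:
    """Dirichlet-multinomial 16S count table.

    Per sample: a library size from a log-normal with the requested mean
    and CV (rounded, floor 1), then a composition drawn Dirichlet with
    concentration ``baseline_concentration`` around the group composition
    (baseline with planted log2 fold changes applied and renormalized),
    then multinomial counts.  Deterministic given the params seed.
    """
    params.validate()
    rng = np.random.default_rng(_substreams(params)["counts"])
    # rank-abundance baseline: Dirichlet draw sorted decreasing, so low
    # indices are the abundant taxa (where effects are typically planted)
    p0 = np.sort(rng.dirichlet(np.ones(params.n_taxa)))[::-1]
    comps = {}
    for g in params.group_sizes:
        lfc = np.zeros(params.n_taxa)
        for pt in params.planted_taxa:
            lfc[pt.index] += pt.fc(g)
        pg = p0 * np.exp2(lfc)
        comps[g] = pg / pg.sum()
    sigma2 = np.log1p(params.library_size_cv ** 2)
    mu = np.log(params.library_size_mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    ids, groups = _sample_index(params)
    rows = np.empty((len(ids), params.n_taxa), dtype=int)
    for i, g in enumerate(groups):
        lib = max(1, int(round(float(rng.lognormal(mu, sigma)))))
        theta = rng.dirichlet(params.baseline_concentration * comps[g])
        rows[i] = rng.multinomial(lib, theta)
    feature_ids = [f"ASV_{j + 1:04d}" for j in range(params.n_taxa)]
    df = pd.DataFrame(rows, index=ids, columns=feature_ids)
    return FeatureTable(df)


def generate_metabolites(params: SimulationParams,
                         counts: FeatureTable | None = None) -> FeatureTable:
    """Log-normal metabolite concentration table.

    Group shifts are planted on the log scale in units of the per-metabolite
    log SD.  Planted taxon-metabolite links blend the linked taxon's
    standardized CSS-normalized log abundance z with independent noise:
    e = r·z + sqrt(1−r²)·ε, which realizes a log-scale Pearson correlation
    of r in expectation (a link with r = 0 leaves the metabolite fully
    independent of the taxon).
    """
    params.validate()
    if params.links and counts is None:
        raise ValueError("counts table required when taxon-metabolite links are planted")
    rng = np.random.default_rng(_substreams(params)["metabolites"])
    ids, groups = _sample_index(params)
    n = len(ids)
    m = params.n_metabolites
    log_medians = rng.normal(1.0, 1.0, size=m)
    eps = rng.standard_normal((n, m))
    z_taxa = {}
    if params.links:
        if counts.n_samples != n:
            raise ValueError("counts table does not match the simulated design")
        css = css_normalize(counts)
        logged = np.log1p(css.values)
        for lk in params.links:
            col = logged[:, lk.taxon]
            sd = col.std(ddof=1)
            if sd == 0:
                raise ValueError(f"linked taxon {lk.taxon} has zero variance")
            z_taxa[lk.metabolite] = (col - col.mean()) / sd
    link_r = {lk.metabolite: lk.r for lk in params.links}
    shifts = np.zeros((n, m))
    for pm in params.planted_metabolites:
        for i, g in enumerate(groups):
            shifts[i, pm.index] += pm.delta(g)
    e = eps.copy()
    for j, r in link_r.items():
        e[:, j] = r * z_taxa[j] + np.sqrt(1 - r ** 2) * eps[:, j]
    logx = log_medians[None, :] + params.metabolite_log_sd * (shifts + e)
    names = [DEFAULT_METABOLITES[j] if j < len(DEFAULT_METABOLITES)
             else f"metabolite_{j + 1}" for j in range(m)]
    df = pd.DataFrame(np.exp(logx), index=ids, columns=names)
    return FeatureTable(df)


def generate_clinical(params: SimulationParams) -> pd.DataFrame:
    """Clinical table via a calibrated Gaussian copula.

    Latent pairwise correlations are calibrated so the output Pearson
    correlations match the spec's targets; the latent matrix is repaired to
    the nearest PSD correlation matrix if calibration breaks definiteness.
    Returns a DataFrame with a ``group`` column plus one column per
    clinical variable, indexed by sample ID.
    """
    params.validate()
    spec = params.clinical
    rng = np.random.default_rng(_substreams(params)["clinical"])
    names = spec.variables
    transforms = {v: spec.marginals[v].transform() for v in names}
    ix = {v: i for i, v in enumerate(names)}
    L = np.eye(len(names))
    for a, b, r in spec.correlations:
        rho = _calibrate_latent_rho(transforms[a], transforms[b], r)
        L[ix[a], ix[b]] = L[ix[b], ix[a]] = rho
    L = _nearest_psd(L)
    chol = np.linalg.cholesky(L + 1e-12 * np.eye(len(names)))
    ids, groups = _sample_index(params)
    Z = rng.standard_normal((len(ids), len(names))) @ chol.T
    data = {v: transforms[v](Z[:, ix[v]]) for v in names}
    df = pd.DataFrame(data, index=ids)
    df.insert(0, "group", groups)
    return df


def synthetic_taxonomy(params: SimulationParams) -> pd.Series:
    """Greengenes-style lineages for the simulated ASVs (deterministic)."""
    lineages = {}
    for j in range(params.n_taxa):
        phylum, family, genus = _TAXON_POOL[j % len(_TAXON_POOL)]
        lineages[f"ASV_{j + 1:04d}"] = (
            f"k__Bacteria; p__{phylum}; f__{family}; g__{genus}")
    return pd.Series(lineages, name="lineage")


@dataclass
class StudyBundle:
    """Linked counts / metabolites / clinical tables with planted truth."""

    counts: FeatureTable
    metabolites: FeatureTable
    clinical: pd.DataFrame
    truth: dict
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.sample_ids
        if self.metabolites.sample_ids != idx or list(self.clinical.index) != idx:
            raise ValueError("tables do not share an identical ordered sample index")
        if (self.counts.values.sum(axis=1) == 0).any():
            raise ValueError("counts table has an all-zero sample")

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids

    @property
    def groups(self) -> np.ndarray:
        return self.clinical["group"].to_numpy()


def generate_study(params: SimulationParams) -> StudyBundle:
    """Generate a fully linked bundle; deterministic given the params seed."""
    params.validate()
    counts = generate_counts(params)
    metabolites = generate_metabolites(params, counts)
    clinical = generate_clinical(params)
    taxon_ids = counts.feature_ids
    met_ids = metabolites.feature_ids
    truth = {
        "planted_taxa": [
            {"index": pt.index, "feature_id": taxon_ids[pt.index],
             "log2_fold_change": dict(pt.log2_fold_change)}
            for pt in params.planted_taxa],
        "planted_metabolites": [
            {"index": pm.index, "feature_id": met_ids[pm.index],
             "shift": dict(pm.shift)}
            for pm in params.planted_metabolites],
        "links": [
            {"taxon": lk.taxon, "taxon_id": taxon_ids[lk.taxon],
             "metabolite": lk.metabolite, "metabolite_id": met_ids[lk.metabolite],
             "r": lk.r}
            for lk in params.links],
        "seed": params.seed,
    }
    return StudyBundle(counts, metabolites, clinical, truth,
                       synthetic_taxonomy(params))


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as TSV tables plus a truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "clinical": outdir / "clinical.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.counts.to_tsv(paths["counts"])
    bundle.metabolites.to_tsv(paths["metabolites"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index_label="sample_id")
    bundle.taxonomy.to_csv(paths["taxonomy"], sep="\t", header=False)
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2))
    return paths


def default_study_params(seed: int = 0) -> SimulationParams:
    """The default synthetic study: planted effects mirroring the kind of
    taxon and metabolite signal a T1D-onset cohort shows.

    Eight taxa carry two-fold (|log2 FC| = 1) changes in the patient group
    (some shared at reduced strength with siblings, emulating familial
    similarity); six metabolites carry ±0.8 SD log-scale shifts; two
    taxon-metabolite links are planted (r = −0.68 and +0.56).
    """
    planted_taxa = (
        PlantedTaxon(0, (("T1D", 1.0), ("sibling", 0.7))),    # Clostridium up
        PlantedTaxon(1, (("T1D", 1.0),)),                      # Lachnospiraceae up
        PlantedTaxon(2, (("T1D", -1.0), ("sibling", -0.7))),   # Dialister down
        PlantedTaxon(3, (("T1D", -1.0), ("sibling", -0.7))),   # Akkermansia down
        PlantedTaxon(4, (("T1D", -1.0),)),                     # Collinsella down
        PlantedTaxon(5, (("T1D", 1.0), ("sibling", 0.7))),     # Dorea up
        PlantedTaxon(6, (("T1D", 1.0),)),                      # Enterobacteriaceae up
        PlantedTaxon(7, (("T1D", -1.0),)),                     # Alistipes down
    )
    met_ix = {m: j for j, m in enumerate(DEFAULT_METABOLITES)}
    planted_metabolites = (
        PlantedMetabolite(met_ix["isobutyrate"], (("T1D", 0.8),)),
        PlantedMetabolite(met_ix["malonate"], (("T1D", 0.8),)),
        PlantedMetabolite(met_ix["butyrate"], (("T1D", -0.8),)),
        PlantedMetabolite(met_ix["ethanol"], (("T1D", -0.8),)),
        PlantedMetabolite(met_ix["succinate"], (("T1D", -0.8),)),
        PlantedMetabolite(met_ix["galactose"], (("T1D", -0.8),)),
    )
    links = (
        TaxonMetaboliteLink(3, met_ix["isobutyrate"], -0.68),  # Akkermansia
        TaxonMetaboliteLink(4, met_ix["butyrate"], 0.56),      # Collinsella
    )
    return SimulationParams(planted_taxa=planted_taxa,
                            planted_metabolites=planted_metabolites,
                            links=links, seed=seed)
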