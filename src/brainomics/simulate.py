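"""Synthetic cohort generator with planted ground truth.

Everything downstream is testable against this module: bulk counts arise
from known per-sample cell-type mixing weights applied to purified
expression profiles, disease effects are planted as per-gene log2 fold
changes (including a reduced-expression effect on genes whose TSS lies
near a planted consensus transcription-factor peak set), observed counts
are distorted by a per-sample alignment-quality covariate (PRUA) through
binomial read thinning, and metabolites are coupled to designated gene
sets at a target correlation. The truth ledger records every planted
quantity so each downstream estimate can be scored.

Counts follow the NB2 convention, variance = mu + alpha * mu^2, with a
shared dispersion alpha by default; alpha = 0 degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GenomicInterval, MetaboliteMatrix, SampleTable
from .normalize import normalize_pipeline
from .peaks import nearest_peak_distance

__all__ = [
    "CellProfilePanel",
    "Coupling",
    "CohortConfig",
    "CohortTruth",
    "SimulatedCohort",
    "make_profiles",
    "sample_pure_counts",
    "make_genome",
    "make_cohort",
    "generate_metabolites",
]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class CellProfilePanel:
    """Purified-cell expression profiles with disjoint marker sets.

    ``mean_expression`` is genes x cell types (positive means); every
    marker gene's mean in its own cell type exceeds its maximum elsewhere
    by at least ``specificity_fold``.
    """

    mean_expression: pd.DataFrame
    marker_map: dict[str, list[str]]
    specificity_fold: float

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expression.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.mean_expression.index


@dataclass(frozen=True)
class Coupling:
    """A metabolite tied to the mean normalized expression of a gene set."""

    metabolite: str
    source_genes: tuple[str, ...]
    rho: float

    def __post_init__(self):
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("coupling rho must lie in (0, 1]")


@dataclass
class CohortConfig:
    """Study conditions for a simulated case/control cohort.

    Defaults emulate a single-region post-mortem cohort: 24 subjects per
    diagnosis group, ~2000 genes, four brain cell types with neurons around
    half the tissue, NB dispersion 0.05, and a planted composition shift
    moving mixing weight from neurons to astrocytes in SZ and BPD.
    """

    diagnoses: tuple[str, ...] = ("CTL", "SZ")
    n_per_group: int = 24
    region: str = "AnCg"
    n_genes: int = 2000
    cell_types: tuple[str, ...] = ("neuron", "astrocyte", "oligodendrocyte", "microglia")
    base_weights: tuple[float, ...] = (0.5, 0.25, 0.15, 0.10)
    weight_concentration: float = 200.0
    neuron_shift: Mapping[str, float] = field(default_factory=dict)  # e.g. {"SZ": -0.1}
    marker_frac: float = 0.02
    specificity_fold: float = 8.0
    total_reads: int = 2_000_000
    dispersion: float = 0.05
    de_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # planted TF-proximity effect: genes with TSS within tf_distance of a
    # consensus peak get tf_lfc added to their case log2 effect
    tf_lfc: float = 0.0
    tf_distance: int = 1000
    tf_diagnoses: tuple[str, ...] = ("SZ",)
    n_peaks: int = 40
    peak_width: int = 400
    n_peak_sets: int = 3
    peak_jitter: int = 50
    n_private_peaks: int = 20
    chrom_length: int = 10_000_000
    # PRUA (fraction of reads uniquely aligned) distribution and distortion.
    # Observed counts are a binomial thinning of the true counts with
    # per-gene retention prua ** sensitivity_g: genes differ in how much
    # signal they lose to alignment quality (sensitivity ~ U(range), mean 1),
    # which is what makes PRUA a genuine covariate rather than a pure
    # depth change the size factors would absorb.
    prua_mean: float = 0.85
    prua_concentration: float = 150.0
    prua_mean_by_dx: Mapping[str, float] = field(default_factory=dict)
    prua_sensitivity_range: tuple[float, float] = (0.5, 1.5)
    # metabolites
    n_metabolites: int = 141
    couplings: tuple[Coupling, ...] = ()
    metabolite_noise_sd: float = 1.0
    metabolite_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


@dataclass
class CohortTruth:
    """Ground-truth ledger sufficient to score every downstream estimate."""

    weights: pd.DataFrame  # samples x cell types, rows sum to 1
    effects: pd.DataFrame  # genes x diagnoses, total planted log2 effect
    tf_targets: list[str]
    tss_distance: pd.Series  # gene -> bp distance to nearest consensus peak
    couplings: tuple[Coupling, ...]
    prua: pd.Series
    prua_sensitivity: pd.Series | None = None  # per-gene thinning exponent


@dataclass
class SimulatedCohort:
    counts: CountMatrix
    samples: SampleTable
    truth: CohortTruth
    panel: CellProfilePanel
    tss: pd.DataFrame
    peak_sets: list[list[GenomicInterval]]
    consensus_truth: list[GenomicInterval]
    metabolites: MetaboliteMatrix | None = None


# ---------------------------------------------------------------------------


def make_profiles(
    n_genes: int,
    cell_types: Sequence[str],
    marker_frac: float = 0.02,
    specificity_fold: float = 8.0,
    seed=0,
) -> CellProfilePanel:
    """Log-normal purified expression profiles with planted marker genes.

    Each cell type gets ``round(marker_frac * n_genes)`` dedicated marker
    genes (disjoint across types); a marker's mean in its own type is set
    to ``specificity_fold`` times its maximum over the other types, so the
    specificity ratio holds by construction.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("cell type names must be unique")
    if n_genes < 100:
        raise ValueError("need n_genes >= 100")
    n_markers = int(round(marker_frac * n_genes))
    if n_markers < 10:
        raise ValueError("marker_frac * n_genes must be >= 10 per cell type")
    if n_markers * len(cell_types) > n_genes:
        raise ValueError("marker sets would overlap: reduce marker_frac")
    rng = _rng(seed)
    genes = _gene_ids(n_genes)
    baseline = rng.lognormal(mean=2.0, sigma=1.2, size=n_genes)
    wiggle = rng.lognormal(mean=0.0, sigma=0.25, size=(n_genes, len(cell_types)))
    means = baseline[:, None] * wiggle

    picks = rng.choice(n_genes, size=n_markers * len(cell_types), replace=False)
    marker_map: dict[str, list[str]] = {}
    for t, cell_type in enumerate(cell_types):
        idx = picks[t * n_markers : (t + 1) * n_markers]
        other = [j for j in range(len(cell_types)) if j != t]
        means[idx, t] = specificity_fold * means[np.ix_(idx, other)].max(axis=1)
        marker_map[cell_type] = sorted(genes[i] for i in idx)

    df = pd.DataFrame(means, index=genes, columns=cell_types)
    return CellProfilePanel(df, marker_map, specificity_fold)


def sample_pure_counts(
    panel: CellProfilePanel,
    cell_type: str,
    total_reads: int,
    dispersion: float = 0.05,
    seed=0,
) -> np.ndarray:
    """Draw a purified-sample count vector for one cell type.

    Negative-binomial per gene with mean proportional to the panel profile
    scaled to approximately ``total_reads``; ``dispersion=0`` gives Poisson
    draws; ``total_reads=0`` the zero vector.
    """
    if cell_type not in panel.mean_expression.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if total_reads == 0:
        return np.zeros(len(panel.gene_ids), dtype=np.int64)
    rng = _rng(seed)
    profile = panel.mean_expression[cell_type].to_numpy(float)
    mu = total_reads * profile / profile.sum()
    return _nb_draw(rng, mu, dispersion)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def make_genome(
    n_genes: int,
    n_peaks: int,
    peak_width: int = 400,
    n_peak_sets: int = 3,
    jitter: int = 0,
    n_private: int = 0,
    chrom_length: int = 10_000_000,
    seed=0,
):
    """A synthetic chromosome with TSSs and replicated peak sets.

    A core set of consensus peaks is present in every replicate set, with
    boundary noise up to ``jitter`` bp; each set additionally receives
    ``n_private`` private peaks. Returns ``(tss_table, peak_sets,
    core_peaks)`` where the TSS table is indexed by gene id and core_peaks
    are the ground-truth consensus intervals.
    """
    if n_peak_sets < 2:
        raise ValueError("need >= 2 peak sets")
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    rng = _rng(seed)
    chrom = "chrS"
    genes = _gene_ids(n_genes)
    tss_pos = np.sort(rng.choice(chrom_length, size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    tss = pd.DataFrame(
        {"chrom": chrom, "tss": tss_pos, "strand": strands},
        index=pd.Index(genes, name="gene_id"),
    )

    core_starts = np.sort(
        rng.choice(chrom_length - peak_width, size=n_peaks, replace=False)
    )
    core = [GenomicInterval(chrom, int(s), int(s + peak_width)) for s in core_starts]

    peak_sets = []
    for _ in range(n_peak_sets):
        ivs = []
        for iv in core:
            if jitter > 0:
                ds = int(rng.integers(-jitter, jitter + 1))
                de = int(rng.integers(-jitter, jitter + 1))
            else:
                ds = de = 0
            start = max(0, iv.start + ds)
            end = min(chrom_length, max(start + 1, iv.end + de))
            ivs.append(GenomicInterval(chrom, start, end))
        for _p in range(n_private):
            s = int(rng.integers(0, chrom_length - peak_width))
            ivs.append(GenomicInterval(chrom, s, s + peak_width))
        peak_sets.append(sorted(ivs, key=lambda i: (i.start, i.end)))
    return tss, peak_sets, core


def make_cohort(config: CohortConfig, seed=0) -> SimulatedCohort:
    """Generate a full case/control cohort with its ground-truth ledger.

    Per sample: mixing weights ~ Dirichlet around the diagnosis-specific
    base composition (the configured neuron shift moves weight from
    neurons to astrocytes in affected groups); expected counts are the
    weight-blended purified profiles scaled to the library size, times the
    planted 2^log2-effect multipliers for case samples; counts are NB
    draws subsequently thinned binomially with per-sample retention PRUA.
    """
    cfg = config
    if cfg.n_per_group < 3:
        raise ValueError("need >= 3 samples per group")
    if len(cfg.base_weights) != len(cfg.cell_types):
        raise ValueError("base_weights must match cell_types")
    rng = _rng(seed)
    panel = make_profiles(
        cfg.n_genes,
        cfg.cell_types,
        cfg.marker_frac,
        cfg.specificity_fold,
        seed=rng,
    )
    genes = list(panel.gene_ids)
    tss, peak_sets, core = make_genome(
        cfg.n_genes,
        cfg.n_peaks,
        cfg.peak_width,
        cfg.n_peak_sets,
        cfg.peak_jitter,
        cfg.n_private_peaks,
        cfg.chrom_length,
        seed=rng,
    )
    dist = nearest_peak_distance(tss, core)
    tf_targets = sorted(dist.index[dist <= cfg.tf_distance]) if cfg.tf_lfc else []

    # total planted per-gene log2 effect, per diagnosis
    effects = pd.DataFrame(0.0, index=genes, columns=list(cfg.diagnoses))
    for dx, table in cfg.de_effects.items():
        for g, lfc in table.items():
            effects.loc[g, dx] += lfc
    if cfg.tf_lfc:
        for dx in cfg.tf_diagnoses:
            if dx in effects.columns:
                effects.loc[tf_targets, dx] += cfg.tf_lfc

    profiles = panel.mean_expression.to_numpy(float)
    profile_props = profiles / profiles.sum(axis=0, keepdims=True)

    sample_ids, rows, weight_rows, count_cols, prua_vals = [], [], [], [], []
    base_w = np.asarray(cfg.base_weights, float)
    base_w = base_w / base_w.sum()
    neuron_idx = 0
    astro_idx = 1 if len(cfg.cell_types) > 1 else 0
    lo, hi = cfg.prua_sensitivity_range
    sensitivity = rng.uniform(lo, hi, size=cfg.n_genes)
    for dx in cfg.diagnoses:
        dx_prua_mean = float(cfg.prua_mean_by_dx.get(dx, cfg.prua_mean))
        a_prua = dx_prua_mean * cfg.prua_concentration
        b_prua = (1 - dx_prua_mean) * cfg.prua_concentration
        shift = float(cfg.neuron_shift.get(dx, 0.0))
        w_dx = base_w.copy()
        w_dx[neuron_idx] += shift
        w_dx[astro_idx] -= shift
        if np.any(w_dx <= 0):
            raise ValueError(f"neuron shift {shift} makes weights non-positive")
        mult = np.exp2(effects[dx].to_numpy())
        for i in range(cfg.n_per_group):
            sid = f"{dx}_{i:03d}"
            sample_ids.append(sid)
            w = rng.dirichlet(cfg.weight_concentration * w_dx)
            weight_rows.append(w)
            mu = cfg.total_reads * (profile_props @ w) * mult
            true_counts = _nb_draw(rng, mu, cfg.dispersion)
            prua = float(rng.beta(a_prua, b_prua))
            prua_vals.append(prua)
            observed = rng.binomial(true_counts, prua**sensitivity)
            count_cols.append(observed)
            rows.append(
                {
                    "diagnosis": dx,
                    "region": cfg.region,
                    "age": float(np.clip(rng.normal(50, 10), 20, 90)),
                    "pH": float(np.clip(rng.normal(6.8, 0.15), 6.5, 7.2)),
                    "PMI": float(np.clip(rng.normal(20, 6), 2, 50)),
                    "PRUA": prua,
                }
            )

    counts = CountMatrix(
        pd.DataFrame(
            np.column_stack(count_cols), index=genes, columns=sample_ids
        )
    )
    samples = SampleTable(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))
    truth = CohortTruth(
        weights=pd.DataFrame(
            np.vstack(weight_rows), index=sample_ids, columns=list(cfg.cell_types)
        ),
        effects=effects,
        tf_targets=tf_targets,
        tss_distance=dist,
        couplings=tuple(cfg.couplings),
        prua=pd.Series(prua_vals, index=sample_ids, name="PRUA"),
        prua_sensitivity=pd.Series(sensitivity, index=genes, name="prua_sensitivity"),
    )
    cohort = SimulatedCohort(counts, samples, truth, panel, tss, peak_sets, core)
    if cfg.n_metabolites > 0:
        cohort.metabolites = generate_metabolites(
            cohort,
            cfg.couplings,
            noise_sd=cfg.metabolite_noise_sd,
            n_metabolites=cfg.n_metabolites,
            group_effects=cfg.metabolite_effects,
            seed=rng,
        )
    return cohort


def generate_metabolites(
    cohort,
    couplings: Sequence[Coupling] = (),
    noise_sd: float = 1.0,
    n_metabolites: int = 141,
    group_effects: Mapping[str, Mapping[str, float]] | None = None,
    seed=0,
) -> MetaboliteMatrix:
    """Metabolite abundances coupled to gene expression at target correlations.

    A coupled metabolite is log-linear in the standardized mean normalized
    expression of its source genes plus Gaussian noise whose scale is
    calibrated so the (log-scale) sample correlation approaches the
    coupling's rho at ``noise_sd=1``; ``noise_sd -> 0`` drives the
    correlation to 1. Uncoupled metabolites are independent log-normals.
    ``group_effects`` plants per-diagnosis multiplicative 2^shift effects
    (metabolite -> diagnosis -> log2 shift) for differential testing.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    if isinstance(cohort, SimulatedCohort):
        norm = normalize_pipeline(cohort.counts)
        expr = norm.values
        diagnoses = cohort.samples.table["diagnosis"]
    else:  # a bare normalized expression frame
        expr = cohort.values if hasattr(cohort, "values") and not isinstance(cohort, pd.DataFrame) else cohort
        diagnoses = None
    sample_ids = expr.columns
    n = len(sample_ids)

    coupled_names = [c.metabolite for c in couplings]
    if len(set(coupled_names)) != len(coupled_names):
        raise ValueError("duplicate coupled metabolite names")
    names = list(coupled_names)
    i = 0
    while len(names) < max(n_metabolites, len(names)):
        cand = f"m{i:04d}"
        if cand not in names:
            names.append(cand)
        i += 1

    data = {}
    for c in couplings:
        missing = [g for g in c.source_genes if g not in expr.index]
        if missing:
            raise ValueError(f"coupling source genes absent: {missing}")
        z = expr.loc[list(c.source_genes)].mean(axis=0).to_numpy()
        sdz = z.std()
        if sdz == 0:
            raise ValueError("source-gene expression is constant; cannot couple")
        z = (z - z.mean()) / sdz
        s = noise_sd * np.sqrt(1.0 / c.rho**2 - 1.0)
        m = z + s * rng.normal(size=n)
        m = m / np.sqrt(1.0 + s**2)
        data[c.metabolite] = np.exp(2.0 + 0.5 * m)
    for name in names:
        if name not in data:
            data[name] = rng.lognormal(mean=2.0, sigma=0.5, size=n)

    ab = pd.DataFrame(data, index=sample_ids).T.loc[names]
    if group_effects:
        if diagnoses is None:
            raise ValueError("group_effects require a cohort with diagnoses")
        for met, table in group_effects.items():
            for dx, shift in table.items():
                cols = diagnoses.index[diagnoses == dx]
                ab.loc[met, cols] = ab.loc[met, cols] * (2.0**shift)
    return MetaboliteMatrix(ab)
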