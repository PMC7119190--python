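"""Synthetic breeding populations for genomic-prediction studies.

Two population structures are generated, mirroring the situations the
toolkit is designed to analyse:

- **Diverged-subpopulation panels** (chickpea-like): two inbred groups whose
  allele frequencies diverge under the Balding-Nichols model at a chosen
  Fst. Each line is a doubled mosaic of a small group-specific founder
  haplotype pool, so marker-QTL linkage disequilibrium (LD) is
  subpopulation specific — the mechanism that makes cross-group genomic
  prediction fail in real diverged panels.
- **Bi-parental DH half-sib families** (maize-like): fully inbred parents,
  one shared across families; each doubled-haploid (DH) line is a single
  F1 gamete (crossovers Poisson on the genetic map, Haldane model, no
  interference) doubled to homozygosity.

Trait architecture: ``n_qtl`` causal loci, per-environment effect vectors
drawn from a centred multivariate normal with correlation ``Gamma`` and
equal variances, independent across QTL. True breeding values are the QTL
dosage sums; plot residual variances are set from the empirical genetic
variance so each environment hits its target plot-level heritability. QTL
are excluded from the emitted marker panel by default (markers tag causal
loci only through LD, as in real data).

All randomness flows from one ``numpy.random.default_rng`` seed; identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import Coding, MarkerMatrix
from .model import PhenotypeTable

__all__ = [
    "SubpopSpec", "FamilySpec", "SimConfig", "TruthSet", "SimData",
    "simulate_founders", "make_dh_family", "assign_qtl_effects",
    "simulate_phenotypes", "simulate_dataset",
    "chickpea_like_preset", "maize_like_preset", "hudson_fst",
]


@dataclass(frozen=True)
class SubpopSpec:
    """Diverged inbred subpopulations (Balding-Nichols frequencies).

    ``sizes`` lines per group; ``fst`` in (0, 1) controls divergence;
    each group draws ``n_founder_haplotypes`` founder haplotypes at its own
    frequencies, and every line is a doubled recombinant mosaic of that
    pool with ``mosaic_generations`` expected crossovers per Morgan.
    """

    sizes: tuple
    fst: float = 0.4
    n_founder_haplotypes: int = 10
    mosaic_generations: float = 5.0
    labels: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"Fst must be in (0, 1), got {self.fst}")
        labels = self.labels or tuple(f"grp{i + 1}"
                                      for i in range(len(self.sizes)))
        if len(labels) != len(self.sizes):
            raise ValueError("one label per group required")
        object.__setattr__(self, "labels", tuple(labels))


@dataclass(frozen=True)
class FamilySpec:
    """Bi-parental DH families: list of (parent_a, parent_b, n_dh)."""

    crosses: tuple

    def __post_init__(self):
        object.__setattr__(self, "crosses",
                           tuple((str(a), str(b), int(n))
                                 for a, b, n in self.crosses))

    @property
    def parent_names(self) -> list:
        seen = []
        for a, b, _ in self.crosses:
            for p in (a, b):
                if p not in seen:
                    seen.append(p)
        return seen


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for one synthetic dataset."""

    n_chromosomes: int = 10
    chrom_length_cm: float = 100.0
    n_markers: int = 1000
    n_qtl: int = 300
    subpop_spec: SubpopSpec | None = None
    family_spec: FamilySpec | None = None
    env_ids: tuple = ("env1", "env2")
    genetic_corr: np.ndarray = None
    plot_h2: tuple = (0.5, 0.5)
    n_reps_per_env: int = 2
    env_means: tuple | None = None
    rep_effect_sd: float = 0.0
    coding: Coding = Coding.BIALLELIC_012
    missing_rate: float = 0.0
    qtl_observed: bool = False
    seed: int = 0

    def __post_init__(self):
        t = len(self.env_ids)
        object.__setattr__(self, "env_ids", tuple(self.env_ids))
        G = self.genetic_corr
        if G is None:
            G = np.eye(t)
        G = np.asarray(G, dtype=float)
        if G.shape != (t, t) or not np.allclose(G, G.T):
            raise ValueError(f"genetic_corr must be symmetric {t}x{t}")
        if not np.allclose(np.diag(G), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(G)[0] <= 0:
            raise ValueError("genetic_corr is not positive definite")
        object.__setattr__(self, "genetic_corr", G)
        h2 = tuple(float(h) for h in self.plot_h2)
        if len(h2) == 1:
            h2 = h2 * t
        if len(h2) != t or any(not 0.0 < h <= 1.0 for h in h2):
            raise ValueError("plot_h2 must be per-environment values in (0, 1]")
        object.__setattr__(self, "plot_h2", h2)
        if self.env_means is not None:
            em = tuple(float(m) for m in self.env_means)
            if len(em) != t:
                raise ValueError("env_means must have one entry per environment")
            object.__setattr__(self, "env_means", em)
        if self.subpop_spec is None and self.family_spec is None:
            raise ValueError("either subpop_spec or family_spec is required")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def t(self) -> int:
        return len(self.env_ids)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    true_bv: pd.DataFrame            # lines x environments
    genetic_corr: np.ndarray         # the target Gamma
    residual_var: np.ndarray         # per-environment plot residual variance
    plot_h2: tuple                   # targets the residuals were set from
    qtl_positions: np.ndarray        # (n_qtl, 2): chromosome, position cM
    qtl_effects: np.ndarray          # (n_qtl, t)
    labels: dict                     # line -> subpopulation or family label

    def realized_h2(self) -> np.ndarray:
        """Var(BV) / (Var(BV) + residual variance), per environment."""
        vg = self.true_bv.var(axis=0, ddof=1).to_numpy()
        return vg / (vg + self.residual_var)


@dataclass(frozen=True)
class SimData:
    """A complete simulated dataset: markers, phenotypes, truth, labels."""

    markers: MarkerMatrix
    pheno: PhenotypeTable
    truth: TruthSet
    labels: dict
    config: SimConfig

    @property
    def family_map(self) -> dict:
        return dict(self.labels)


# ---------------------------------------------------------------------------
# genome scaffolding


def _draw_positions(rng, n_loci: int, n_chrom: int, length_cm: float):
    """Uniform locus positions: array of (chromosome, cM), sorted."""
    chrom = rng.integers(0, n_chrom, size=n_loci)
    pos = rng.uniform(0.0, length_cm, size=n_loci)
    order = np.lexsort((pos, chrom))
    return np.column_stack([chrom, pos])[order]


def _gamete_origins(positions: np.ndarray, rng,
                    rate_per_morgan: float = 1.0) -> np.ndarray:
    """Which of two parental haplotypes each locus comes from (0/1).

    Crossovers are a Poisson process on map distance (Haldane, no
    interference): per chromosome the crossover count is Poisson with mean
    ``rate_per_morgan * length_cm / 100`` and breakpoint positions uniform.
    """
    origins = np.empty(len(positions), dtype=np.int8)
    for ch in np.unique(positions[:, 0]):
        sel = positions[:, 0] == ch
        pos = positions[sel, 1]
        length = pos.max() if len(pos) else 0.0
        n_x = rng.poisson(rate_per_morgan * length / 100.0)
        breaks = np.sort(rng.uniform(0.0, length, size=n_x))
        start = rng.integers(0, 2)
        origins[sel] = (start + np.searchsorted(breaks, pos)) % 2
    return origins


def _mosaic_haplotype(pool: np.ndarray, positions: np.ndarray, rng,
                      rate_per_morgan: float) -> np.ndarray:
    """One haplotype as a recombinant mosaic of a founder pool.

    Segment switches follow the same Poisson-on-map process as gametes, but
    each segment's source is drawn uniformly from the pool — a cheap stand-in
    for several generations of random mating within a closed population.
    """
    n_loci = len(positions)
    src = np.empty(n_loci, dtype=np.int64)
    for ch in np.unique(positions[:, 0]):
        sel = positions[:, 0] == ch
        pos = positions[sel, 1]
        length = pos.max() if len(pos) else 0.0
        n_x = rng.poisson(rate_per_morgan * length / 100.0)
        breaks = np.sort(rng.uniform(0.0, length, size=n_x))
        seg = np.searchsorted(breaks, pos)
        seg_sources = rng.integers(0, len(pool), size=n_x + 1)
        src[sel] = seg_sources[seg]
    return pool[src, np.arange(n_loci)]


# ---------------------------------------------------------------------------
# founders and families


def simulate_founders(config: SimConfig, rng=None):
    """Founder haplotypes and line labels for the configured population.

    For subpopulation panels: ancestral frequencies ~ Uniform(0.1, 0.9);
    group frequencies ~ Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F); each
    line is a doubled mosaic of its group's founder haplotype pool.
    For family panels: parents are fully inbred lines sampled at the
    ancestral frequencies.

    Returns
    -------
    haplotypes : ndarray (n_lines_or_parents, n_loci) of 0/1
    labels : dict line -> group label (empty for family parents)
    positions : ndarray (n_loci, 2)
    """
    rng = rng or np.random.default_rng(config.seed)
    n_loci = config.n_markers + config.n_qtl
    positions = _draw_positions(rng, n_loci, config.n_chromosomes,
                                config.chrom_length_cm)
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    if config.subpop_spec is not None:
        sp = config.subpop_spec
        fst = sp.fst
        haps, labels = [], {}
        line_no = 0
        for size, label in zip(sp.sizes, sp.labels):
            a = p0 * (1.0 - fst) / fst
            b = (1.0 - p0) * (1.0 - fst) / fst
            p_grp = rng.beta(a, b)
            pool = (rng.uniform(size=(sp.n_founder_haplotypes, n_loci))
                    < p_grp).astype(np.int8)
            for _ in range(size):
                hap = _mosaic_haplotype(pool, positions, rng,
                                        sp.mosaic_generations)
                haps.append(hap)
                labels[f"L{line_no:04d}"] = label
                line_no += 1
        return np.array(haps), labels, positions
    fam = config.family_spec
    parents = fam.parent_names
    haps = (rng.uniform(size=(len(parents), n_loci)) < p0).astype(np.int8)
    return haps, {}, positions


def make_dh_family(parent_a: np.ndarray, parent_b: np.ndarray, n_dh: int,
                   positions: np.ndarray, rng) -> np.ndarray:
    """Doubled-haploid progeny of a bi-parental cross.

    Each DH line is one recombinant F1 gamete — crossovers placed by a
    Poisson process on map distance (Haldane mapping, no interference) —
    with its haplotype doubled, so every line is fully homozygous and the
    expected parent-a allele share is 0.5 at every locus.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    for p, name in ((parent_a, "a"), (parent_b, "b")):
        if not np.isin(p, (0, 1)).all():
            raise ValueError(f"parent {name} is not a homozygous 0/1 haplotype")
    out = np.empty((n_dh, len(positions)), dtype=np.int8)
    stacked = np.stack([parent_a, parent_b])
    for i in range(n_dh):
        origins = _gamete_origins(positions, rng)
        out[i] = stacked[origins, np.arange(len(positions))]
    return out


# ---------------------------------------------------------------------------
# trait architecture


def assign_qtl_effects(config: SimConfig, rng=None) -> np.ndarray:
    """Per-QTL, per-environment additive effects.

    Each QTL's length-t effect vector is centred multivariate normal with
    correlation ``Gamma`` and unit per-environment variance; QTL are
    independent of each other.
    """
    rng = rng or np.random.default_rng(config.seed)
    G = config.genetic_corr
    if np.linalg.eigvalsh(G)[0] <= 0:
        raise ValueError("genetic_corr is not positive definite")
    L = np.linalg.cholesky(G)
    return rng.standard_normal((config.n_qtl, config.t)) @ L.T


def simulate_phenotypes(line_ids, qtl_dosages: np.ndarray,
                        qtl_effects: np.ndarray, config: SimConfig,
                        rng=None):
    """Plot records and truth from QTL genotypes and effects.

    True breeding values are ``g = qtl_dosages @ qtl_effects``; each
    environment's plot residual variance is
    ``Var(g_e) * (1 - h2_e) / h2_e`` with the variance taken empirically
    over the simulated lines, so the realized plot-level heritability
    matches its target up to sampling error. ``n_reps_per_env`` plots are
    recorded per line and environment, with optional additive replicate
    effects.
    """
    rng = rng or np.random.default_rng(config.seed)
    g = qtl_dosages @ qtl_effects
    n, t = g.shape
    var_g = g.var(axis=0, ddof=1)
    if (var_g <= 0).any():
        j = int(np.argmin(var_g))
        raise ValueError(f"zero genetic variance in {config.env_ids[j]!r}")
    h2 = np.array(config.plot_h2)
    res_var = var_g * (1.0 - h2) / h2
    env_means = np.array(config.env_means) if config.env_means is not None \
        else np.zeros(t)
    records = []
    for j, e in enumerate(config.env_ids):
        sd = np.sqrt(res_var[j])
        for r in range(config.n_reps_per_env):
            rep_eff = (rng.normal(0.0, config.rep_effect_sd)
                       if config.rep_effect_sd > 0 else 0.0)
            noise = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
            vals = env_means[j] + rep_eff + g[:, j] + noise
            for i, l in enumerate(line_ids):
                records.append((l, e, f"rep{r + 1}", vals[i]))
    pheno = PhenotypeTable(pd.DataFrame(
        records, columns=["line", "env", "rep", "value"]))
    true_bv = pd.DataFrame(g, index=list(line_ids),
                           columns=list(config.env_ids))
    return pheno, true_bv, res_var


# ---------------------------------------------------------------------------
# end-to-end dataset


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimData:
    """Generate one complete dataset (markers, phenotypes, truth, labels)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_loci = config.n_markers + config.n_qtl

    if config.subpop_spec is not None:
        haps, labels, positions = simulate_founders(config, rng)
        line_ids = list(labels)
        genotypes = 2 * haps            # doubled mosaics: inbred lines
    else:
        parent_haps, _, positions = simulate_founders(config, rng)
        fam = config.family_spec
        parents = {name: parent_haps[i]
                   for i, name in enumerate(fam.parent_names)}
        rows, line_ids, labels = [], [], {}
        for a, b, n_dh in fam.crosses:
            fam_label = f"{a}x{b}"
            dh = make_dh_family(parents[a], parents[b], n_dh, positions, rng)
            rows.append(2 * dh)
            for i in range(n_dh):
                lid = f"{fam_label}_{i:03d}"
                line_ids.append(lid)
                labels[lid] = fam_label
        genotypes = np.vstack(rows)

    # split loci into emitted markers and (by default unobserved) QTL
    loci = rng.permutation(n_loci)
    qtl_idx = np.sort(loci[:config.n_qtl])
    marker_idx = np.sort(loci[config.n_qtl:])
    qtl_dosages = genotypes[:, qtl_idx].astype(float)  # dosage scale 0/2
    effects = assign_qtl_effects(config, rng)

    emit_idx = np.sort(np.concatenate([marker_idx, qtl_idx])) \
        if config.qtl_observed else marker_idx
    emitted = genotypes[:, emit_idx].astype(float)
    if config.coding is Coding.DOMINANT_01:
        emitted = emitted / 2.0
    marker_ids = tuple(f"M{positions[j, 0].astype(int)}_{j:05d}"
                       for j in emit_idx)
    if config.missing_rate > 0:
        mask = rng.uniform(size=emitted.shape) < config.missing_rate
        emitted = np.where(mask, np.nan, emitted)
    markers = MarkerMatrix(tuple(line_ids), marker_ids, emitted,
                           config.coding)

    pheno, true_bv, res_var = simulate_phenotypes(
        line_ids, qtl_dosages, effects, config, rng)
    truth = TruthSet(true_bv, config.genetic_corr.copy(), res_var,
                     config.plot_h2, positions[qtl_idx], effects,
                     dict(labels))
    return SimData(markers, pheno, truth, dict(labels), config)


# ---------------------------------------------------------------------------
# presets


def chickpea_like_preset(n_per_group=(153, 162), n_markers: int = 2600,
                         n_qtl: int = 100, fst: float = 0.4,
                         plot_h2: float = 0.35,
                         genetic_corr_offdiag: float = 0.5,
                         n_reps: int = 3, seed: int = 0) -> SimConfig:
    """Two diverged inbred seed-type groups in two water regimes.

    Defaults emulate a 153 + 162 line panel with ~2,600 biallelic markers,
    rainfed/irrigated environments with three replicates each, Fst 0.4
    between groups, across-environment genetic correlation 0.5 and plot
    heritability 0.35. All sizes are overridable for scaled-down runs.
    """
    t = 2
    G = np.full((t, t), genetic_corr_offdiag)
    np.fill_diagonal(G, 1.0)
    return SimConfig(
        n_chromosomes=8, chrom_length_cm=100.0,
        n_markers=n_markers, n_qtl=n_qtl,
        subpop_spec=SubpopSpec(sizes=tuple(n_per_group), fst=fst,
                               labels=("kabuli", "desi")),
        env_ids=("rainfed", "irrigated"), genetic_corr=G,
        plot_h2=(plot_h2,) * t, n_reps_per_env=n_reps,
        env_means=(0.0, 2.0), coding=Coding.BIALLELIC_012,
        missing_rate=0.02, seed=seed)


def maize_like_preset(family_sizes=(91, 108, 88), n_markers: int = 6800,
                      n_qtl: int = 300, plot_h2=(0.30, 0.25, 0.30),
                      genetic_corr_offdiag=(0.54, 0.72, 0.40),
                      n_reps: int = 2, seed: int = 0) -> SimConfig:
    """Three DH half-sib families sharing one parent, three environments.

    Defaults emulate 91/108/88 DH lines genotyped with ~6,800 dominant 0/1
    markers, tested with two replicates in a main, a second and a managed
    drought environment; genetic correlations (0.54, 0.72, 0.40) between
    (main, second), (main, drought) and (second, drought), plot
    heritabilities (0.30, 0.25, 0.30). All sizes are overridable.
    """
    r12, r13, r23 = genetic_corr_offdiag
    G = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    crosses = tuple(("P0", f"P{i + 1}", n)
                    for i, n in enumerate(family_sizes))
    return SimConfig(
        n_chromosomes=10, chrom_length_cm=150.0,
        n_markers=n_markers, n_qtl=n_qtl,
        family_spec=FamilySpec(crosses),
        env_ids=("main", "second", "drought"), genetic_corr=G,
        plot_h2=tuple(plot_h2), n_reps_per_env=n_reps,
        env_means=(0.0, 1.0, -2.0), coding=Coding.DOMINANT_01,
        missing_rate=0.02, seed=seed)


# ---------------------------------------------------------------------------
# diagnostics


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Hudson's Fst estimator averaged over loci.

    Inputs are dosage matrices (lines x loci) on the 0/2 (inbred) or 0/1/2
    scale; frequencies are taken as mean dosage / 2. Uses the ratio of
    averages, with the standard sample-size correction for within-group
    heterozygosity of haploid-equivalent frequencies.
    """
    pa = geno_a.mean(axis=0) / 2.0
    pb = geno_b.mean(axis=0) / 2.0
    na, nb = len(geno_a), len(geno_b)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
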