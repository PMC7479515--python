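"""Synthetic single-cell and bulk cohorts with planted ground truth.

The generator emulates the data a single-cell tumor-heterogeneity study works
from, with every latent quantity recorded so downstream stages can be scored
against truth:

* a genome of genes partitioned over chromosomes with p/q arms, carrying named
  gene modules: normal-cell-type marker sets (microglia, T cell, OPC,
  oligodendrocyte, endothelial analogues), malignant expression programs
  including S-phase and G2M cycling modules, and a housekeeping set;
* multi-sample cohorts of malignant cells that up-regulate their program's
  module and carry chromosome-arm copy-number multipliers, interspersed with
  normal cells expressing their marker modules and carrying no CNAs;
* log-normal baseline gene abundance with negative-binomial count noise,
  renormalized to TPM per cell;
* a binarized regulon-activity matrix whose regulons fire preferentially in
  target programs;
* a bulk cohort whose expression is a composition-weighted mixture of program
  profiles and whose survival hazard is log-linear in the fraction of a target
  program.

Copy number acts multiplicatively on expected expression *before* count
sampling, so the dosage signal a moving-average CNA method detects is present
at the level the counts are drawn from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneAnnotation

NORMAL_TYPES = ("microglia", "t_cell", "opc", "oligodendrocyte", "endothelial")
CYCLING_MODULES = ("S", "G2M")


@dataclass
class GenomeSpec:
    """Gene universe with chromosome/arm layout, modules, and baseline means.

    ``annotation`` is indexed by gene id with columns ``chromosome``, ``arm``,
    ``start``, ``end``.  ``modules`` maps module name -> list of member gene
    ids (mutually disjoint; all disjoint from ``housekeeping``).
    ``base_mean`` is the expected relative abundance of each gene in a cell
    with no module active, drawn log-normally.
    """

    annotation: pd.DataFrame
    modules: dict[str, list[str]] = field(default_factory=dict)
    housekeeping: list[str] = field(default_factory=list)
    base_mean: pd.Series | None = None
    seed: int = 0

    @property
    def gene_ids(self) -> pd.Index:
        return self.annotation.index

    @property
    def n_genes(self) -> int:
        return len(self.annotation)

    def arm_genes(self, chromosome: str, arm: str) -> pd.Index:
        mask = (self.annotation["chromosome"] == chromosome) & (self.annotation["arm"] == arm)
        return self.annotation.index[mask]

    def validate(self) -> None:
        if self.annotation.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        claimed: set[str] = set(self.housekeeping)
        for name, genes in self.modules.items():
            gset = set(genes)
            if not gset <= set(self.gene_ids):
                raise ValueError(f"module {name!r} contains genes outside the universe")
            if gset & claimed:
                raise ValueError(f"module {name!r} overlaps another module or housekeeping")
            claimed |= gset
        for _, chrom_tab in self.annotation.groupby("chromosome"):
            starts = chrom_tab["start"].to_numpy()
            if not (np.diff(np.sort(starts)) > 0).all():
                raise ValueError("gene positions must strictly increase within a chromosome")

    def gene_annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.annotation.copy())


@dataclass
class SampleDesign:
    """Cell composition of one synthetic sample.

    ``malignant`` maps program name -> number of malignant cells assigned to
    it; ``normal`` maps normal cell type -> count.  ``cna_events`` lists
    (chromosome, arm, multiplier) applied to every malignant cell of the
    sample.  ``cycling_fraction`` of malignant cells additionally activate the
    S or G2M module (chosen at random per cell).
    """

    sample_id: str
    compartment: str = "PF"
    malignant: dict[str, int] = field(default_factory=dict)
    normal: dict[str, int] = field(default_factory=dict)
    cna_events: list[tuple[str, str, float]] = field(default_factory=list)
    cycling_fraction: float = 0.0


@dataclass
class NoiseParams:
    """Count-noise configuration.

    ``dispersion`` is the negative-binomial overdispersion phi (variance =
    mu + phi*mu^2); 0 gives Poisson counts.  ``lib_size`` is the expected
    total count per cell.
    """

    dispersion: float = 0.15
    lib_size: int = 150_000


def make_genome(
    n_genes: int,
    n_chromosomes: int,
    module_sizes: dict[str, int] | None = None,
    seed: int = 0,
    n_housekeeping: int = 50,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
    hk_boost: float = 5.0,
) -> GenomeSpec:
    """Build a deterministic synthetic genome.

    Genes are split into ``n_chromosomes`` contiguous blocks; each chromosome
    gets a ``p`` and ``q`` arm at its midpoint.  ``module_sizes`` maps module
    name -> gene count; modules and the housekeeping set are disjoint random
    subsets of the universe.  Housekeeping baseline means are boosted by
    ``hk_boost`` so their expression is stably high, as QC assumes.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if module_sizes is None:
        module_sizes = {}
    total_module = sum(module_sizes.values()) + n_housekeeping
    if total_module > n_genes:
        raise ValueError(
            f"module sizes ({total_module} genes incl. housekeeping) exceed universe ({n_genes})"
        )

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    chrom_of = np.array_split(np.arange(n_genes), n_chromosomes)
    rows = []
    for ci, idx in enumerate(chrom_of):
        name = f"chr{ci + 1}"
        half = len(idx) // 2
        for j, gi in enumerate(idx):
            start = j * 1000
            rows.append((gene_ids[gi], name, "p" if j < half else "q", start, start + 500))
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "arm", "start", "end"]
    ).set_index("gene_id")
    annotation = annotation.loc[gene_ids]

    perm = rng.permutation(n_genes)
    cursor = 0
    housekeeping = [gene_ids[i] for i in perm[cursor : cursor + n_housekeeping]]
    cursor += n_housekeeping
    modules: dict[str, list[str]] = {}
    for name, size in module_sizes.items():
        modules[name] = sorted(gene_ids[i] for i in perm[cursor : cursor + size])
        cursor += size

    base = pd.Series(rng.lognormal(meanlog, sdlog, n_genes), index=gene_ids, name="base_mean")
    base[housekeeping] *= hk_boost

    genome = GenomeSpec(
        annotation=annotation,
        modules=modules,
        housekeeping=sorted(housekeeping),
        base_mean=base,
        seed=seed,
    )
    genome.validate()
    return genome


def _resolve_fold(fold_change, module: str) -> float:
    f = fold_change.get(module, 1.0) if isinstance(fold_change, dict) else float(fold_change)
    if f <= 0:
        raise ValueError(f"fold change for {module!r} must be positive")
    return f


def expected_profile(
    genome: GenomeSpec,
    program: str | None = None,
    normal_type: str | None = None,
    cna_events=(),
    fold_change=4.0,
    cycling_module: str | None = None,
) -> pd.Series:
    """Expected (pre-noise) expression of one cell, normalized to TPM."""
    mu = genome.base_mean.copy()
    active = [m for m in (program, normal_type, cycling_module) if m is not None]
    for mod in active:
        if mod not in genome.modules:
            raise KeyError(f"unknown module {mod!r}")
        mu[genome.modules[mod]] *= _resolve_fold(fold_change, mod)
    for chrom, arm, mult in cna_events:
        if mult <= 0:
            raise ValueError("CNA multiplier must be positive")
        genes = genome.arm_genes(chrom, arm)
        if len(genes) == 0:
            raise ValueError(f"no genes on {chrom}{arm}")
        mu[genes] *= mult
    return mu / mu.sum() * 1e6


def simulate_cells(
    genome: GenomeSpec,
    design: list[SampleDesign],
    noise: NoiseParams | None = None,
    seed: int = 0,
    fold_change=4.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneAnnotation]:
    """Draw a multi-sample cohort of cells.

    Returns the TPM matrix (cell groups = compartments), a truth table indexed
    by cell id (``sample_id``, ``compartment``, ``cell_class``, ``program``,
    ``cycling``, ``cna_events``), and the gene annotation.

    Counts are negative-binomial around each cell's expected profile scaled to
    ``noise.lib_size`` total, then renormalized so each cell's TPM sums to 1e6.
    """
    if not design:
        raise ValueError("empty design")
    noise = noise or NoiseParams()
    if noise.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)

    mus, records = [], []
    for sd in design:
        for ntype, n in sd.normal.items():
            prof = expected_profile(genome, normal_type=ntype, fold_change=fold_change)
            for _ in range(n):
                mus.append(prof)
                records.append((sd.sample_id, sd.compartment, f"normal:{ntype}", None, False, ()))
        for prog, n in sd.malignant.items():
            base = expected_profile(
                genome, program=prog, cna_events=sd.cna_events, fold_change=fold_change
            )
            n_cyc = int(round(sd.cycling_fraction * n))
            cyc_flags = np.zeros(n, bool)
            cyc_flags[rng.choice(n, size=n_cyc, replace=False)] = True
            for is_cyc in cyc_flags:
                if is_cyc:
                    cmod = CYCLING_MODULES[rng.integers(2)]
                    mus.append(
                        expected_profile(
                            genome,
                            program=prog,
                            cna_events=sd.cna_events,
                            fold_change=fold_change,
                            cycling_module=cmod,
                        )
                    )
                else:
                    mus.append(base)
                records.append(
                    (sd.sample_id, sd.compartment, "malignant", prog, bool(is_cyc),
                     tuple(sd.cna_events))
                )

    mu_mat = np.vstack([m.to_numpy() for m in mus])
    lam = mu_mat / mu_mat.sum(axis=1, keepdims=True) * noise.lib_size
    if noise.dispersion > 0:
        shape = 1.0 / noise.dispersion
        lam = rng.gamma(shape, lam * noise.dispersion)
    counts = rng.poisson(lam).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    tpm = counts / totals * 1e6

    cell_ids = [f"C{i:05d}" for i in range(len(records))]
    truth = pd.DataFrame(
        records,
        index=pd.Index(cell_ids, name="cell_id"),
        columns=["sample_id", "compartment", "cell_class", "program", "cycling", "cna_events"],
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=cell_ids, columns=genome.gene_ids),
        "tpm",
        truth["compartment"],
    )
    return matrix, truth, genome.gene_annotation()


def simulate_regulons(
    cell_truth: pd.DataFrame,
    regulon_design: dict[str, dict],
    flip_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary cells x regulons activity matrix.

    ``regulon_design`` maps regulon name -> ``{"targets": [program, ...],
    "p_on": float, "p_off": float}``; a regulon is active with probability
    ``p_on`` in cells whose program is a target, ``p_off`` (default 0)
    elsewhere.  Each entry is then flipped with probability ``flip_noise``.
    """
    if not 0 <= flip_noise <= 1:
        raise ValueError("flip_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    programs = cell_truth["program"]
    for name, cfg in regulon_design.items():
        p_on = float(cfg.get("p_on", 1.0))
        p_off = float(cfg.get("p_off", 0.0))
        if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
            raise ValueError(f"regulon {name!r}: probabilities must be in [0, 1]")
        p = np.where(programs.isin(cfg.get("targets", [])), p_on, p_off)
        act = rng.random(len(p)) < p
        if flip_noise > 0:
            act ^= rng.random(len(p)) < flip_noise
        out[name] = act.astype(int)
    return pd.DataFrame(out, index=cell_truth.index)


def simulate_bulk_cohort(
    genome: GenomeSpec,
    n_samples: int,
    programs: list[str],
    target_program: str,
    beta: float,
    composition_prior=None,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
    fold_change=4.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk samples as program mixtures with survival tied to one program.

    Each sample's composition over ``programs`` is Dirichlet.  By default
    (``composition_prior=None``) the cohort is a two-component mixture
    mirroring high- and low-expressing bulk tumors: half the samples draw
    their composition from a Dirichlet concentrated on the target program
    (alpha 12 for the target, 1 elsewhere) and half from one depleted of it
    (alpha 1 for the target, 6 elsewhere).  Passing an explicit alpha vector
    gives a single-component Dirichlet cohort instead.

    Expression is the composition-weighted mixture of the program mean
    profiles with multiplicative log-normal noise, renormalized to TPM.
    Survival time is exponential with hazard
    ``baseline_hazard * exp(beta * fraction_of_target_program)``; censoring is
    an independent exponential calibrated to ``censor_rate``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if target_program not in programs:
        raise ValueError("target_program must be listed in programs")

    rng = np.random.default_rng(seed)
    t_idx = programs.index(target_program)
    if composition_prior is None:
        alpha_hi = np.ones(len(programs))
        alpha_hi[t_idx] = 12.0
        alpha_lo = np.full(len(programs), 6.0)
        alpha_lo[t_idx] = 1.0
        planted_high = rng.random(n_samples) < 0.5
        comp = np.where(
            planted_high[:, None],
            rng.dirichlet(alpha_hi, size=n_samples),
            rng.dirichlet(alpha_lo, size=n_samples),
        )
    else:
        alpha = np.asarray(composition_prior, dtype=float)
        if (alpha[alpha > 0]).size <= 1:
            warnings.warn("degenerate composition prior: all mass on one program")
            alpha = np.clip(alpha, 1e-12, None)
        comp = rng.dirichlet(alpha, size=n_samples)
        planted_high = None

    profiles = np.vstack(
        [
            expected_profile(genome, program=p, fold_change=fold_change).to_numpy()
            for p in programs
        ]
    )
    expr = comp @ profiles
    expr *= rng.lognormal(0.0, noise_sd, expr.shape)
    expr = expr / expr.sum(axis=1, keepdims=True) * 1e6

    frac = comp[:, programs.index(target_program)]
    hazard = baseline_hazard * np.exp(beta * frac)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        cens_hazard = baseline_hazard * censor_rate / max(1e-12, 1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / cens_hazard, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    sample_ids = [f"B{i:04d}" for i in range(n_samples)]
    truth = pd.DataFrame(
        {f"frac_{p}": comp[:, j] for j, p in enumerate(programs)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth["target_fraction"] = frac
    if planted_high is not None:
        truth["planted_group"] = np.where(planted_high, "high", "low")
    truth["time"] = time
    truth["event"] = event
    truth["beta"] = beta
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=sample_ids, columns=genome.gene_ids), "tpm"
    )
    return matrix, truth
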