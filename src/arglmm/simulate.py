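"""Synthetic-data harness: coalescent ARGs, phenotypes, comparison GRMs.

ARGs come from msprime coalescent simulations of a panmictic population
that (looking backward in time) starts at 100,000 diploids and shrinks
at 1% per generation, with recombination at 1e-8 per bp per generation —
the regime the estimation benchmarks are run in.  Phenotypes follow the
generative ARG model: genetic values from Gaussian sub-edge effects (or
discrete mutation effects), scaled by ``sqrt(4 * sum_T s_T t_root,T)``
so the genetic and environmental variances are comparable, plus
independent Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .arg import ArgData, total_root_area
from .grm import simulate_genetic_values

__all__ = [
    "SimParams",
    "PhenotypeSimSpec",
    "simulate_arg",
    "simulate_phenotypes",
    "snp_grm",
    "montecarlo_grm_matvec",
    "structured_fixture",
]


@dataclass(frozen=True)
class SimParams:
    """Coalescent simulation settings for the benchmark demography."""

    n_diploids: int = 100
    sequence_length: float = 1e6
    recombination_rate: float = 1e-8
    #: present-day population size; None selects constant size
    initial_size: float = 1e5
    #: backward decline rate per generation (continuous compounding)
    growth_rate: float = 0.01
    mutation_rate: float = 1e-8
    seed: int = 1

    def __post_init__(self):
        if self.n_diploids < 2:
            raise ValueError("need at least 2 diploids")
        for r in (self.recombination_rate, self.mutation_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Phenotype model: y = tau * g_scaled + e, e ~ N(0, sige2).

    ``mode="subedge"`` draws Gaussian sub-edge effects on the ARG
    (covariance exactly tau2 * B before scaling); ``mode="mutation"``
    drops mutations on the ARG, marks ``causal_fraction`` of them causal
    with standard-normal effects, and sums dosages.  Either way the raw
    genetic value is divided by ``sqrt(4 * sum_T span_T * t_root,T)``,
    bounding its haploid variance contribution by roughly the
    environmental scale.
    """

    tau2: float = 1.0
    sigma_e2: float = 1.0
    mode: str = "subedge"
    causal_fraction: float = 0.01
    mutation_rate: float = 1e-8

    def __post_init__(self):
        if self.tau2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.mode not in ("subedge", "mutation"):
            raise ValueError(f"unknown phenotype mode {self.mode!r}")


def _msprime_seed(seed: int) -> int:
    return int(seed) % (2**31 - 2) + 1


def simulate_arg(params: SimParams) -> ArgData:
    """Coalescent ARG for ``2 * n_diploids`` haplotypes in diploid individuals."""
    if params.growth_rate != 0.0 and params.initial_size is not None:
        demography = msprime.Demography()
        demography.add_population(
            initial_size=params.initial_size, growth_rate=params.growth_rate
        )
        demog_kwargs = {"demography": demography}
    else:
        demog_kwargs = {"population_size": params.initial_size or 1e4}
    ts = msprime.sim_ancestry(
        samples=params.n_diploids,
        sequence_length=params.sequence_length,
        recombination_rate=params.recombination_rate,
        random_seed=_msprime_seed(params.seed),
        **demog_kwargs,
    )
    return ArgData(ts)


def simulate_phenotypes(
    arg: ArgData, spec: PhenotypeSimSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate (y, g_scaled) plus the true components and GRM scale.

    Returns ``(y, g, info)`` where ``g`` is the scaled genetic value and
    ``info`` records the generating components and the factor
    ``grm_scale = 1/(4 sum_T s_T t_root,T)`` that puts the branch GRM on
    the same scale (so refitting with that scale recovers ``tau2``).
    """
    area = total_root_area(arg)
    if area <= 0:
        raise ValueError("empty ARG: zero total root area")
    scaling = np.sqrt(4.0 * area)
    rng = np.random.default_rng(seed)
    if spec.mode == "subedge":
        g_raw = simulate_genetic_values(
            arg, tau2=1.0, seed=int(rng.integers(2**31))
        )
    else:
        g_raw = _mutation_genetic_values(arg, spec, rng)
    g = np.sqrt(spec.tau2) * g_raw / scaling
    eps = rng.normal(0.0, np.sqrt(spec.sigma_e2), size=arg.num_individuals)
    y = g + eps
    info = {
        "tau2": spec.tau2,
        "sigma_e2": spec.sigma_e2,
        "grm_scale": 1.0 / (4.0 * area),
        "scaling": scaling,
        "mode": spec.mode,
    }
    return y, g, info


def _mutation_genetic_values(
    arg: ArgData, spec: PhenotypeSimSpec, rng: np.random.Generator
) -> np.ndarray:
    """Discrete-effect genetic values: causal mutations, N(0,1) effects."""
    mts = msprime.sim_mutations(
        arg.ts,
        rate=spec.mutation_rate,
        random_seed=_msprime_seed(int(rng.integers(2**31))),
        discrete_genome=False,
    )
    n_mut = mts.num_mutations
    if n_mut == 0:
        return np.zeros(arg.num_individuals)
    causal = rng.random(n_mut) < spec.causal_fraction
    effects = np.where(causal, rng.standard_normal(n_mut), 0.0)
    g = np.zeros(arg.num_individuals)
    mut_iter = iter(enumerate(mts.mutations()))
    item = next(mut_iter, None)
    for tree in mts.trees():
        while item is not None:
            j, mut = item
            pos = mts.site(mut.site).position
            if pos >= tree.interval.right:
                break
            if effects[j] != 0.0:
                for s in tree.samples(mut.node):
                    g[arg.node_individual[s]] += effects[j]
            item = next(mut_iter, None)
    return g


# ----------------------------------------------------------------------
# comparison GRMs
# ----------------------------------------------------------------------


def snp_grm(genotypes: np.ndarray, maf_min: float = 0.005) -> np.ndarray:
    """Standard SNP GRM from a diploid dosage matrix (individuals x variants).

    ``GRM_ij = (1/M) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))``
    over the M variants with minor allele frequency >= ``maf_min``
    (monomorphic variants always dropped).
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be individuals x variants")
    p = G.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = (maf >= maf_min) & (p > 0) & (p < 1)
    if not np.any(keep):
        raise ValueError("no variants left after the MAF filter")
    Gk = G[:, keep]
    pk = p[keep]
    Xc = (Gk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    return (Xc @ Xc.T) / Gk.shape[1]


def montecarlo_grm_matvec(
    arg: ArgData, mu: float, w: np.ndarray, seed: int
) -> np.ndarray:
    """Monte-Carlo branch-GRM product from random infinite-sites mutations.

    Drops Poisson mutations on the ARG at rate ``mu`` per bp per
    generation (so each sub-edge carries Poisson(mu * A_e) mutations),
    forms the unnormalized genotype cross-product GRM implicitly, and
    returns its product with ``w``; the expectation over seeds is
    ``mu * B w``.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    w = np.asarray(w, dtype=float).ravel()
    n = arg.num_individuals
    if len(w) != n:
        raise ValueError("weight length must equal the number of individuals")
    v = np.zeros(n)
    if mu == 0.0:
        return v
    mts = msprime.sim_mutations(
        arg.ts, rate=mu, random_seed=_msprime_seed(seed), discrete_genome=False
    )
    sites = mts.tables.sites.position
    tree = None
    for mut in mts.mutations():
        pos = sites[mut.site]
        if tree is None or not (tree.interval.left <= pos < tree.interval.right):
            tree = mts.at(pos)
        z = np.zeros(n)
        for s in tree.samples(mut.node):
            z[arg.node_individual[s]] += 1.0
        v += z * (z @ w)
    return v


def structured_fixture(
    n_demes: int = 16,
    migration_rate: float = 1e-3,
    n_diploids: int = 64,
    sequence_length: float = 5e5,
    recombination_rate: float = 1e-8,
    deme_size: float = 500.0,
    seed: int = 1,
) -> ArgData:
    """Stepping-stone ARG with strong fine-scale structure.

    A reduced stand-in for spatially continuous simulations: low
    migration between many demes yields a GRM whose spectrum decays more
    slowly (top eigenvalue carries a smaller share of the trace) than a
    panmictic ARG of equal size, the regime that stresses randomized
    linear algebra.  ``n_demes=1`` reduces to the panmictic fixture.
    """
    if n_diploids % n_demes:
        raise ValueError("n_diploids must divide evenly across demes")
    if n_demes == 1:
        demography = msprime.Demography.isolated_model([deme_size])
        samples = {"pop_0": n_diploids}
    else:
        demography = msprime.Demography.stepping_stone_model(
            [deme_size] * n_demes, migration_rate=migration_rate, boundaries=True
        )
        samples = {f"pop_{i}": n_diploids // n_demes for i in range(n_demes)}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        random_seed=_msprime_seed(seed),
    )
    return ArgData(ts)
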