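"""Reproducible simulation experiments on the sharing-versus-relatedness law.

These drivers wire the generator, the filters and the sharing-curve
statistics together for the two headline behaviours:

* with only rare founder-transmitted variants and local-control
  subtraction active, the shared candidate count drops ~50% per halving of
  the expected shared genome fraction;
* adding a locally common variant pool (invisible to public catalogues)
  flattens the curve when the local control is withheld, and not when it
  is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import local_control_filter, public_maf_filter
from .relatedness import (
    ReductionResult,
    SharingCurve,
    reduction_per_halving,
    shared_count_curve,
)
from .simulate import (
    FamilySim,
    SimulationConfig,
    chain_pedigree,
    simulate_pedigree_genotypes,
    simulate_population,
)

__all__ = [
    "chain_sharing_curve",
    "rare_sharing_experiment",
    "subtraction_contrast",
]


def _chain_sim(
    seed: int,
    n_rare: int,
    n_local_common: int,
    n_members: int,
    control_n: int,
):
    cfg = SimulationConfig(
        seed=seed,
        n_global_common=0,
        n_local_common=n_local_common,
        n_rare=n_rare,
        control_n=control_n,
        plant_causal=False,
    )
    rng = np.random.default_rng(seed)
    pop = simulate_population(cfg, rng)
    ped, members, founder = chain_pedigree(n_members)
    # the studied founder is heterozygous for the whole rare pool, so the
    # rare variants all descend along the chain from one haplotype
    force = {founder: pop.af_class == "rare"}
    sim = simulate_pedigree_genotypes(cfg, ped, pop, rng, force_het=force)
    return sim, ped, members, founder


def chain_sharing_curve(
    seed: int,
    n_rare: int = 20_000,
    n_local_common: int = 0,
    n_members: int = 8,
    control_n: int = 300,
    subtract_local: bool = True,
    min_members: int = 2,
) -> SharingCurve:
    """Shared-count curve over prefixes of a transmission chain.

    ``n_rare`` variants are heterozygous in the chain's founder; each
    successive member is one meiosis further, so the expected shared
    fraction halves per member.  Optional locally common variants are
    drawn Hardy–Weinberg in every founder.  With ``subtract_local``, any
    variant present in the simulated control cohort is removed first.
    """
    sim, ped, members, founder = _chain_sim(
        seed, n_rare, n_local_common, n_members, control_n
    )
    matrix = sim.matrix
    if subtract_local:
        surviving = local_control_filter(
            matrix.variants, sim.population.control, "presence", 0
        )
        matrix = matrix.subset_variants(surviving)
    return shared_count_curve(
        matrix, members[:n_members], ped, founder, min_members=min_members
    )


def rare_sharing_experiment(
    seed: int,
    n_replicates: int = 10,
    n_rare: int = 20_000,
    n_members: int = 8,
    control_n: int = 300,
) -> tuple[float, list[ReductionResult]]:
    """Mean percent reduction per halving over replicate chain simulations.

    Rare founder variants only, local subtraction on; prefixes of
    2..``n_members`` members span ``n_members - 2`` halvings.  Returns the
    replicate-mean percentage and the individual results.
    """
    results = []
    for r in range(n_replicates):
        curve = chain_sharing_curve(
            seed=(seed + r) % (2**31 - 1),
            n_rare=n_rare,
            n_local_common=0,
            n_members=n_members,
            control_n=control_n,
            subtract_local=True,
        )
        results.append(reduction_per_halving(curve))
    return float(np.mean([r.percent for r in results])), results


def subtraction_contrast(
    seed: int,
    n_rare: int = 5_000,
    n_local_common: int = 3_000,
    n_members: int = 7,
    control_n: int = 300,
) -> tuple[float, float]:
    """Reduction per halving with vs. without local-control subtraction, on
    the SAME simulated genotypes.

    The variant pool mixes rare founder variants with locally common ones
    carried into the pedigree by every married-in founder.  Returns
    (percent_with_subtraction, percent_without)."""
    sim, ped, members, founder = _chain_sim(
        seed, n_rare, n_local_common, n_members, control_n
    )
    curves = {}
    for label, subtract in (("with", True), ("without", False)):
        matrix = sim.matrix
        if subtract:
            surviving = local_control_filter(
                matrix.variants, sim.population.control, "presence", 0
            )
            matrix = matrix.subset_variants(surviving)
        curves[label] = shared_count_curve(
            matrix, members[:n_members], ped, founder, min_members=2
        )
    return (
        reduction_per_halving(curves["with"]).percent,
        reduction_per_halving(curves["without"]).percent,
    )
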