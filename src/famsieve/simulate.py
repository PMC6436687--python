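"""Synthetic founder population, pedigree transmission and control cohort.

The generator reproduces the statistical structure the filtering strategy
relies on, so every stage of the analysis can run without restricted data:

* three allele-frequency classes — globally common variants (present and
  common in public catalogues), locally common variants (common in the
  regional founder population but absent from public catalogues: the
  signature of a young, expanded population), and rare/private variants;
* Mendelian transmission of founder haplotypes through an arbitrary
  pedigree, either independently per variant or in recombination-free
  per-chromosome segments (so co-founder variants co-segregate as a
  haplotype block);
* a planted dominant causal variant with configurable penetrance and a
  sporadic-phenocopy rate (default 4.5%, a colorectal-cancer-scale
  lifetime risk);
* a control cohort drawn Hardy–Weinberg from the local frequencies.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, write_ped
from .variants import (
    FrequencyResource,
    GenotypeMatrix,
    VariantKey,
    write_frequency_table,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "FamilySim",
    "simulate_population",
    "simulate_pedigree_genotypes",
    "assign_phenotypes",
    "write_outputs",
    "chain_pedigree",
    "branching_pedigree",
]

PUBLIC_RESOURCE_NAMES = ("1000g", "ESP", "ExAC", "UK10K", "GoNL", "deCODE")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults are sized after the emulated study: a 300-individual control
    cohort, a 4.5% sporadic (phenocopy) rate, incomplete penetrance, and a
    variant pool dominated by globally common variation with a substantial
    locally common excess invisible to public catalogues.
    """

    seed: int = 0
    n_global_common: int = 50_000
    n_local_common: int = 5_000
    n_rare: int = 20_000
    global_common_af: tuple[float, float] = (0.05, 0.5)
    local_common_af: tuple[float, float] = (0.02, 0.2)
    rare_af: tuple[float, float] = (0.0001, 0.001)
    penetrance: float = 0.9
    phenocopy_rate: float = 0.045
    control_n: int = 300
    plant_causal: bool = True
    causal_chrom: str = "chr20"
    transmission_mode: str = "per_variant_independent"  # or "segment"
    n_chromosomes: int = 22

    def __post_init__(self) -> None:
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if not 0.0 <= self.phenocopy_rate < 1.0:
            raise ValueError("phenocopy_rate must be in [0, 1)")
        if self.transmission_mode not in ("per_variant_independent", "segment"):
            raise ValueError(f"invalid transmission_mode {self.transmission_mode!r}")
        if min(self.n_global_common, self.n_local_common, self.n_rare) < 0:
            raise ValueError("variant counts must be non-negative")
        if self.rare_af[1] > 0.001:
            raise ValueError("rare-class AF must stay <= 0.001")
        if self.global_common_af[0] <= 0.01:
            raise ValueError("global-common AF must exceed the 1% public threshold")


@dataclass
class Population:
    """Founder-population frequencies, public catalogues and control cohort."""

    variants: list[VariantKey]
    chroms: np.ndarray  # chromosome index per variant (for segment mode)
    local_af: np.ndarray
    af_class: np.ndarray  # 'global_common' | 'local_common' | 'rare'
    public_resources: dict[str, FrequencyResource]
    control: GenotypeMatrix
    causal_index: int | None

    @property
    def causal_variant(self) -> VariantKey | None:
        return None if self.causal_index is None else self.variants[self.causal_index]

    def local_af_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "af": self.local_af,
                "class": self.af_class,
            }
        )


@dataclass
class FamilySim:
    """Simulated family genotypes plus the causal-variant truth sidecar."""

    matrix: GenotypeMatrix
    haplotypes: dict[str, np.ndarray]  # id -> (n_variants, 2) bool
    truth: dict  # causal key, per-individual carrier status
    population: Population


def _random_variants(
    rng: np.random.Generator, n: int, n_chromosomes: int, prefix: str = "chr"
) -> tuple[list[VariantKey], np.ndarray]:
    """Unique keys with increasing positions per chromosome; SNVs only."""
    chrom_idx = np.sort(rng.integers(0, n_chromosomes, size=n))
    variants: list[VariantKey] = []
    pos = np.zeros(n, dtype=np.int64)
    for c in range(n_chromosomes):
        mask = chrom_idx == c
        k = int(mask.sum())
        if not k:
            continue
        pos[mask] = 10_000 + np.cumsum(rng.integers(100, 20_000, size=k))
    refs = _BASES[rng.integers(0, 4, size=n)]
    alts = _BASES[(rng.integers(1, 4, size=n) + rng.integers(0, 4, size=n)) % 4]
    for i in range(n):
        alt = alts[i]
        if alt == refs[i]:  # ensure ref != alt
            alt = _BASES[(list(_BASES).index(refs[i]) + 1) % 4]
        variants.append(
            VariantKey(f"{prefix}{chrom_idx[i] + 1}", int(pos[i]), str(refs[i]), str(alt))
        )
    return variants, chrom_idx


def simulate_population(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw the founder-population frequency landscape and control cohort.

    Globally common variants appear in every public catalogue with a
    jittered frequency above the 1% threshold; locally common and rare
    variants are absent from all public catalogues.  Control genotypes are
    two Bernoulli(local AF) haplotypes per individual (Hardy–Weinberg).
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_global_common + config.n_local_common + config.n_rare
    variants, chrom_idx = _random_variants(rng, n, config.n_chromosomes)
    af_class = np.array(
        ["global_common"] * config.n_global_common
        + ["local_common"] * config.n_local_common
        + ["rare"] * config.n_rare
    )
    # interleave classes across the genome
    perm = rng.permutation(n)
    af_class = af_class[perm]

    local_af = np.empty(n)
    for cls, (lo, hi) in (
        ("global_common", config.global_common_af),
        ("local_common", config.local_common_af),
        ("rare", config.rare_af),
    ):
        mask = af_class == cls
        local_af[mask] = rng.uniform(lo, hi, size=int(mask.sum()))

    causal_index: int | None = None
    if config.plant_causal and config.n_rare > 0:
        on_chrom = np.flatnonzero(
            (af_class == "rare")
            & np.array([v.chrom == config.causal_chrom for v in variants])
        )
        pool = on_chrom if on_chrom.size else np.flatnonzero(af_class == "rare")
        causal_index = int(pool[rng.integers(0, pool.size)])

    public_resources: dict[str, FrequencyResource] = {}
    common_mask = af_class == "global_common"
    common_idx = np.flatnonzero(common_mask)
    for name in PUBLIC_RESOURCE_NAMES:
        jitter = rng.uniform(0.8, 1.2, size=common_idx.size)
        public_af = np.clip(local_af[common_idx] * jitter, 0.011, 0.99)
        public_resources[name] = FrequencyResource(
            name=name,
            mode="maf_threshold",
            threshold=0.01,
            entries={
                variants[i]: float(public_af[k]) for k, i in enumerate(common_idx)
            },
        )

    haps = rng.random((n, config.control_n, 2)) < local_af[:, None, None]
    dosage = haps.sum(axis=2).astype(np.int8)
    control = GenotypeMatrix(
        variants,
        [f"CTRL{j:04d}" for j in range(config.control_n)],
        dosage,
        pd.DataFrame({"FILTER": ["PASS"] * n, "QUAL": [100.0] * n}),
    )
    return Population(
        variants=variants,
        chroms=chrom_idx,
        local_af=local_af,
        af_class=af_class,
        public_resources=public_resources,
        control=control,
        causal_index=causal_index,
    )


def simulate_pedigree_genotypes(
    config: SimulationConfig,
    ped: Pedigree,
    population: Population,
    rng: np.random.Generator | None = None,
    causal_founder: str | None = None,
    force_het: Mapping[str, np.ndarray] | None = None,
) -> FamilySim:
    """Drop founder haplotypes through the pedigree.

    Founders draw two Bernoulli(local AF) haplotypes; the designated
    ``causal_founder`` (first founder by default) is forced heterozygous
    for the planted causal variant.  ``force_het`` maps founder ids to
    boolean variant masks forced heterozygous regardless of frequency
    (used to study the transmission of a known founder haplotype).  Each meiosis transmits one of the two
    parental haplotypes — chosen independently per variant in
    ``per_variant_independent`` mode, or once per chromosome in ``segment``
    mode, in which case all variants a founder carries on one chromosome
    copy travel together (no recombination).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(population.variants)
    af = population.local_af
    haplotypes: dict[str, np.ndarray] = {}
    founders = ped.founders
    if population.causal_index is not None:
        causal_founder = causal_founder or founders[0]
        if causal_founder not in founders:
            raise ValueError(f"{causal_founder!r} is not a founder")

    def gamete(parent: str) -> np.ndarray:
        hp = haplotypes[parent]
        if config.transmission_mode == "per_variant_independent":
            choice = rng.random(n) < 0.5
        else:
            per_chrom = rng.random(config.n_chromosomes) < 0.5
            choice = per_chrom[population.chroms]
        return np.where(choice, hp[:, 0], hp[:, 1])

    for iid in ped.ids:  # topological order
        ind = ped[iid]
        if ind.is_founder:
            hp = rng.random((n, 2)) < af[:, None]
            if force_het and iid in force_het:
                mask = np.asarray(force_het[iid], dtype=bool)
                hp[mask, 0] = True
                hp[mask, 1] = False
            if population.causal_index is not None:
                ci = population.causal_index
                hp[ci, :] = False
                if iid == causal_founder:
                    hp[ci, 0] = True
            haplotypes[iid] = hp
        else:
            haplotypes[iid] = np.stack(
                [gamete(ind.father_id), gamete(ind.mother_id)], axis=1
            )

    samples = ped.ids
    dosage = np.stack(
        [haplotypes[iid].sum(axis=1).astype(np.int8) for iid in samples], axis=1
    )
    matrix = GenotypeMatrix(
        population.variants,
        samples,
        dosage,
        pd.DataFrame({"FILTER": ["PASS"] * n, "QUAL": [100.0] * n}),
    )
    truth: dict = {"causal_variant": None, "carriers": {}}
    if population.causal_index is not None:
        ci = population.causal_index
        truth["causal_variant"] = str(population.variants[ci])
        truth["carriers"] = {
            iid: bool(haplotypes[iid][ci].any()) for iid in samples
        }
    return FamilySim(
        matrix=matrix, haplotypes=haplotypes, truth=truth, population=population
    )


def assign_phenotypes(
    ped: Pedigree,
    carriers: Mapping[str, bool],
    penetrance: float,
    phenocopy_rate: float,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Affection labels: carriers are affected with probability ``penetrance``,
    non-carriers with probability ``phenocopy_rate`` (sporadic cases)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = {}
    for iid in ped.ids:
        p = penetrance if carriers.get(iid, False) else phenocopy_rate
        labels[iid] = "affected" if rng.random() < p else "unaffected"
    return labels


def relabel_pedigree(ped: Pedigree, labels: Mapping[str, str]) -> Pedigree:
    """A copy of the pedigree with new affection labels."""
    return Pedigree(
        [
            Individual(
                id=i.id,
                father_id=i.father_id,
                mother_id=i.mother_id,
                sex=i.sex,
                affection=labels.get(i.id, i.affection),
            )
            for i in ped.members
        ],
        family_id=ped.family_id,
    )


# ---------------------------------------------------------------------------
# Pedigree builders
# ---------------------------------------------------------------------------


def chain_pedigree(n_links: int, family_id: str = "CHAIN") -> tuple[Pedigree, list[str], str]:
    """A transmission chain: founder couple, then each member marries in a
    new spouse and has one child.  Returns (pedigree, chain member ids
    M1..Mn each one meiosis further from the founder, founder id)."""
    if n_links < 1:
        raise ValueError("need at least one link")
    inds = [
        Individual("F0", sex="male"),
        Individual("S0", sex="female"),
    ]
    members = []
    father, mother = "F0", "S0"
    for k in range(1, n_links + 1):
        child = f"M{k}"
        inds.append(Individual(child, father_id=father, mother_id=mother, sex="male"))
        members.append(child)
        if k < n_links:
            spouse = f"S{k}"
            inds.append(Individual(spouse, sex="female"))
            father, mother = child, spouse
    return Pedigree(inds, family_id=family_id), members, "F0"


def branching_pedigree(
    n_generations: int = 3,
    children_per_couple: int = 3,
    family_id: str = "FAM",
) -> tuple[Pedigree, str]:
    """A descending tree from one founder couple; every descendant marries a
    new founder spouse.  Returns (pedigree, ancestral founder id)."""
    inds = [Individual("G0-1", sex="male"), Individual("G0-1s", sex="female")]
    couples = [("G0-1", "G0-1s")]
    counter = 0
    for g in range(1, n_generations + 1):
        next_couples = []
        for father, mother in couples:
            for _ in range(children_per_couple):
                counter += 1
                child = f"G{g}-{counter}"
                inds.append(
                    Individual(
                        child,
                        father_id=father,
                        mother_id=mother,
                        sex="male" if counter % 2 else "female",
                    )
                )
                if g < n_generations:
                    spouse = child + "s"
                    inds.append(
                        Individual(
                            spouse, sex="female" if counter % 2 else "male"
                        )
                    )
                    next_couples.append(
                        (child, spouse) if counter % 2 else (spouse, child)
                    )
        couples = next_couples
    return Pedigree(inds, family_id=family_id), "G0-1"


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------


def write_outputs(sim: FamilySim, ped: Pedigree, outdir: str | Path) -> dict[str, Path]:
    """Write family.vcf, controls.vcf, family.ped, resources/*.tsv, local_af.tsv
    and truth.json; all round-trip through the readers in :mod:`.variants`."""
    outdir = Path(outdir)
    (outdir / "resources").mkdir(parents=True, exist_ok=True)
    paths = {
        "family_vcf": outdir / "family.vcf",
        "controls_vcf": outdir / "controls.vcf",
        "family_ped": outdir / "family.ped",
        "local_af": outdir / "local_af.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(sim.matrix, paths["family_vcf"])
    write_vcf(sim.population.control, paths["controls_vcf"])
    write_ped(ped, paths["family_ped"])
    sim.population.local_af_table().to_csv(paths["local_af"], sep="\t", index=False)
    for name, res in sim.population.public_resources.items():
        p = outdir / "resources" / f"{name}.tsv"
        write_frequency_table(res, p)
        paths[f"resource_{name}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    return paths
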