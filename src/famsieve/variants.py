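"""VCF ingestion, variant normalization and allele-frequency resources.

All variants are reduced to a normalized biallelic key (chrom, pos, ref,
alt) — multiallelic records are decomposed, shared suffix/prefix bases are
trimmed, and indels are left-aligned when a reference window is supplied —
so that family genotypes, control-cohort genotypes and every external
frequency table join on the same identity.

Genotypes are stored as an alternate-allele dosage matrix (0/1/2, -1 for
missing).  The disease model is autosomal dominant, so downstream filtering
collapses dosage to carrier status (any dosage >= 1); the dosage itself is
kept for allele-count bookkeeping and round-tripping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "GenotypeMatrix",
    "FrequencyResource",
    "NormalizationError",
    "VcfFormatError",
    "FrequencyLoadError",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "quality_filter",
    "load_frequency_table",
]

_DNA = frozenset("ACGTN")

MISSING = np.int8(-1)


class NormalizationError(ValueError):
    """Allele pair cannot be reduced to a valid minimal representation."""


class VcfFormatError(ValueError):
    """VCF lacks required fields (e.g. GT) or a requested sample."""


class FrequencyLoadError(ValueError):
    """Frequency table malformed or internally inconsistent."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic variant identity; the join key across resources."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _check_allele(allele: str) -> str:
    a = allele.upper()
    if not a or set(a) - _DNA:
        raise NormalizationError(f"invalid allele {allele!r}")
    return a


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: str | None = None,
    reference_start: int = 1,
) -> VariantKey:
    """Reduce (chrom, pos, ref, alt) to its minimal left-aligned form.

    Right-trims a shared trailing base, left-trims shared leading bases
    (advancing ``pos``), and, when a reference sequence window is supplied
    (``reference`` starting at 1-based ``reference_start``), left-aligns
    indels by extending to the left while the trailing bases still match.
    Idempotent.
    """
    ref = _check_allele(ref)
    alt = _check_allele(alt)
    if ref == alt:
        raise NormalizationError(f"ref and alt identical at {chrom}:{pos}")

    changed = True
    while changed:
        changed = False
        # trim shared trailing base
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # left-align: trailing bases equal but one allele is length 1
        if ref[-1] == alt[-1]:
            if reference is None:
                break  # cannot extend without sequence context
            left = pos - 1
            idx = left - reference_start
            if idx < 0 or idx >= len(reference):
                break
            base = reference[idx].upper()
            ref = base + ref[:-1]
            alt = base + alt[:-1]
            pos = left
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:
        raise NormalizationError(f"empty allele after trimming at {chrom}:{pos}")
    return VariantKey(chrom=str(chrom), pos=int(pos), ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Alt-allele dosage per variant and sample, with per-variant metadata.

    ``dosage[i, j]`` is the number of alternate alleles sample ``j`` carries
    at variant ``i`` (-1 = missing).  Metadata carries at least FILTER and
    QUAL when the matrix came from a VCF.
    """

    def __init__(
        self,
        variants: Sequence[VariantKey],
        samples: Sequence[str],
        dosage: np.ndarray,
        metadata: pd.DataFrame | None = None,
    ):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosage = dosage
        if metadata is None:
            metadata = pd.DataFrame(index=range(len(variants)))
        self.metadata = metadata.reset_index(drop=True)
        self._variant_index = {v: i for i, v in enumerate(self.variants)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    # -- shape / lookup ----------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_index(self, key: VariantKey) -> int:
        return self._variant_index[key]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._variant_index

    def sample_columns(self, sample_ids: Iterable[str]) -> list[int]:
        try:
            return [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    # -- carrier view (dominant-model collapse) -----------------------------

    @property
    def carrier(self) -> np.ndarray:
        """Ternary carrier codes: 1 carrier (dosage >= 1), 0 non-carrier, -1 missing."""
        codes = (self.dosage > 0).astype(np.int8)
        codes[self.dosage == MISSING] = MISSING
        return codes

    def carrier_counts(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        """Number of carrier individuals per variant among the given samples."""
        cols = (
            slice(None) if sample_ids is None else self.sample_columns(sample_ids)
        )
        return (self.dosage[:, cols] > 0).sum(axis=1)

    def noncarrier_counts(
        self,
        sample_ids: Iterable[str],
        missing_as_noncarrier: bool = True,
    ) -> np.ndarray:
        """Per-variant count of samples that do NOT carry the alternate allele.

        With ``missing_as_noncarrier`` (the conservative default for
        segregation filtering) a missing genotype counts against the
        variant; otherwise missing genotypes are ignored.
        """
        cols = self.sample_columns(sample_ids)
        sub = self.dosage[:, cols]
        if missing_as_noncarrier:
            return (sub <= 0).sum(axis=1)
        return (sub == 0).sum(axis=1)

    def allele_counts(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        cols = (
            slice(None) if sample_ids is None else self.sample_columns(sample_ids)
        )
        sub = self.dosage[:, cols]
        return np.where(sub > 0, sub, 0).sum(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing genotypes."""
        called = (self.dosage != MISSING).sum(axis=1)
        ac = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, ac / (2.0 * called), np.nan)

    # -- subsetting ---------------------------------------------------------

    def subset_variants(self, which: Iterable[VariantKey] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(which, np.ndarray) and which.dtype == bool:
            idx = np.flatnonzero(which)
        else:
            idx = np.array([self._variant_index[k] for k in which], dtype=int)
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            self.samples,
            self.dosage[idx],
            self.metadata.iloc[idx] if len(self.metadata.columns) else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = self.sample_columns(sample_ids)
        return GenotypeMatrix(
            self.variants, list(sample_ids), self.dosage[:, cols], self.metadata
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosage,
            index=[str(v) for v in self.variants],
            columns=self.samples,
        )
        return df


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    reference: str | None = None,
    reference_start: int = 1,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic sites are decomposed into one record per alternate allele
    before normalization; per-sample dosages count only that allele, so the
    decomposed records sum to the original allele counts.  Missing
    genotypes stay missing.  Metadata columns: FILTER, QUAL.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise VcfFormatError(f"samples not in VCF header: {missing}")
        samples = list(sample_subset)
    else:
        samples = header_samples
    cols = [header_samples.index(s) for s in samples]

    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    meta_filter: list[str] = []
    meta_qual: list[float] = []
    for rec in vcf:
        if rec.FORMAT and "GT" not in rec.FORMAT:
            raise VcfFormatError(f"record {rec.CHROM}:{rec.POS} lacks GT")
        if not rec.FORMAT:
            raise VcfFormatError("VCF has no GT FORMAT field")
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        filt = rec.FILTER or "PASS"  # cyvcf2 reports PASS as None
        qual = rec.QUAL if rec.QUAL is not None else np.nan
        for ai, alt in enumerate(rec.ALT, start=1):
            key = normalize_variant(
                rec.CHROM, rec.POS, rec.REF, alt, reference, reference_start
            )
            row = np.zeros(len(cols), dtype=np.int8)
            for j, c in enumerate(cols):
                alleles = gts[c][:-1]
                if all(a == -1 for a in alleles):
                    row[j] = MISSING
                else:
                    row[j] = sum(1 for a in alleles if a == ai)
            variants.append(key)
            rows.append(row)
            meta_filter.append(filt)
            meta_qual.append(qual)
    dosage = (
        np.stack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    metadata = pd.DataFrame({"FILTER": meta_filter, "QUAL": meta_qual})
    return GenotypeMatrix(variants, samples, dosage, metadata)


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 that round-trips the dosage matrix."""
    contigs: list[str] = []
    for v in matrix.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    has_meta = set(matrix.metadata.columns) >= {"FILTER", "QUAL"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famsieve\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FILTER=<ID=LowQual,Description="Below quality threshold">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, v in enumerate(matrix.variants):
            if has_meta:
                qual = matrix.metadata["QUAL"].iloc[i]
                qual_s = "." if pd.isna(qual) else f"{qual:g}"
                filt = matrix.metadata["FILTER"].iloc[i]
            else:
                qual_s, filt = ".", "PASS"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosage[i])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual_s}\t{filt}\t.\tGT\t{gts}\n"
            )


def quality_filter(
    matrix: GenotypeMatrix,
    min_qual: float | None = None,
    keep_filters: frozenset[str] = frozenset({"PASS", "."}),
) -> GenotypeMatrix:
    """Drop records failing FILTER (anything not PASS/'.') or below ``min_qual``."""
    if "FILTER" not in matrix.metadata.columns:
        raise ValueError("matrix has no FILTER metadata")
    keep = matrix.metadata["FILTER"].isin(keep_filters).to_numpy()
    if min_qual is not None:
        qual = matrix.metadata["QUAL"].to_numpy(dtype=float)
        keep &= ~(qual < min_qual)  # NaN QUAL ('.') passes
    return matrix.subset_variants(keep)


# ---------------------------------------------------------------------------
# Frequency resources
# ---------------------------------------------------------------------------

MODES = ("maf_threshold", "presence", "max_carriers")


@dataclass
class FrequencyResource:
    """Named allele-frequency lookup with its filtering semantics.

    ``mode`` states how a filter should use the resource: remove variants
    whose frequency exceeds a threshold (``maf_threshold``), remove any
    variant present at all (``presence``), or remove variants carried by
    more than a threshold number of individuals (``max_carriers``; requires
    carrier counts, available when the resource was built from genotypes or
    the table carries allele counts).
    """

    name: str
    mode: str = "maf_threshold"
    threshold: float = 0.01
    entries: dict[VariantKey, float] = field(default_factory=dict)
    allele_counts: dict[VariantKey, int] = field(default_factory=dict)
    carrier_counts: dict[VariantKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"invalid mode {self.mode!r}")
        bad = [k for k, af in self.entries.items() if not (0.0 <= af <= 1.0)]
        if bad:
            raise FrequencyLoadError(f"allele frequency outside [0,1] for {bad[0]}")

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def af(self, key: VariantKey) -> float | None:
        return self.entries.get(key)

    def carriers(self, key: VariantKey) -> int | None:
        if key in self.carrier_counts:
            return self.carrier_counts[key]
        # fall back on allele count: an upper bound equal to it only if all
        # carriers are heterozygous, which holds for the rare variants this
        # mode is used on
        return self.allele_counts.get(key)

    @classmethod
    def from_genotype_matrix(
        cls,
        matrix: GenotypeMatrix,
        name: str,
        mode: str = "presence",
        threshold: float = 0.0,
    ) -> "FrequencyResource":
        af = matrix.allele_frequencies()
        ac = matrix.allele_counts()
        carriers = matrix.carrier_counts()
        present = ac > 0
        return cls(
            name=name,
            mode=mode,
            threshold=threshold,
            entries={
                v: float(af[i])
                for i, v in enumerate(matrix.variants)
                if present[i]
            },
            allele_counts={
                v: int(ac[i]) for i, v in enumerate(matrix.variants) if present[i]
            },
            carrier_counts={
                v: int(carriers[i])
                for i, v in enumerate(matrix.variants)
                if present[i]
            },
        )


def load_frequency_table(
    path: str | Path,
    name: str,
    mode: str = "maf_threshold",
    threshold: float = 0.01,
) -> FrequencyResource:
    """Load a frequency resource from TSV (chrom,pos,ref,alt,af[,ac]) or sites VCF.

    Keys are normalized before insertion so un-normalized rows are still
    found by normalized queries.  Duplicate keys with conflicting
    frequencies are a load error.
    """
    path = Path(path)
    entries: dict[VariantKey, float] = {}
    acs: dict[VariantKey, int] = {}

    def insert(key: VariantKey, af: float, ac: int | None) -> None:
        if key in entries and not np.isclose(entries[key], af):
            raise FrequencyLoadError(
                f"{name}: duplicate key {key} with conflicting af "
                f"({entries[key]} vs {af})"
            )
        entries[key] = af
        if ac is not None:
            acs[key] = int(ac)

    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF

        for rec in VCF(str(path)):
            afs = rec.INFO.get("AF")
            if afs is None:
                raise FrequencyLoadError(f"{name}: sites VCF lacks AF INFO tag")
            if not isinstance(afs, tuple):
                afs = (afs,)
            for alt, af in zip(rec.ALT, afs):
                insert(normalize_variant(rec.CHROM, rec.POS, rec.REF, alt), float(af), None)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos", "ref", "alt", "af"}
        if not required <= set(df.columns):
            raise FrequencyLoadError(
                f"{name}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        has_ac = "ac" in df.columns
        for row in df.itertuples(index=False):
            key = normalize_variant(row.chrom, int(row.pos), row.ref, row.alt)
            ac = row.ac if has_ac else None
            insert(key, float(row.af), None if ac is None or pd.isna(ac) else int(ac))
    return FrequencyResource(
        name=name, mode=mode, threshold=threshold, entries=entries, allele_counts=acs
    )


def write_frequency_table(resource: FrequencyResource, path: str | Path) -> None:
    rows = []
    for key in sorted(resource.entries):
        rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "af": resource.entries[key],
                "ac": resource.allele_counts.get(key, ""),
            }
        )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af", "ac"]).to_csv(
        path, sep="\t", index=False
    )
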