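"""Characterization of surviving candidate variants.

Covers three reporting operations on a filtered candidate set: genomic
context classification against a simple gene model (exon/intron/upstream/
intergenic interval logic), novelty relative to an rsID catalogue (a
candidate with no database identifier is novel), and single-linkage
positional clustering, which summarizes candidates that travel on one
founder haplotype into a small number of genomic blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .variants import VariantKey

__all__ = [
    "Transcript",
    "GeneModel",
    "CandidateRecord",
    "Cluster",
    "classify_genomic_context",
    "novelty_classification",
    "cluster_candidates",
    "load_candidate_table",
    "load_packaged_candidates",
]

CONTEXTS = ("exonic", "intron", "upstream_gene", "intergenic")


@dataclass(frozen=True)
class Transcript:
    """Transcript span with exons; coordinates 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"exon ({s},{e}) outside transcript span of {self.gene}"
                )


class GeneModel:
    """Per-gene transcript and exon intervals used for context classification."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneModel":
        """BED12: 0-based half-open input, converted to 1-based inclusive."""
        transcripts = []
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"BED12 line with {len(f)} fields: {line!r}")
                chrom, cstart, cend, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (cstart + s + 1, cstart + s + sz)
                    for s, sz in zip(starts, sizes)
                )
                transcripts.append(
                    Transcript(
                        gene=name,
                        chrom=chrom,
                        start=cstart + 1,
                        end=cend,
                        strand=strand,
                        exons=exons,
                    )
                )
        return cls(transcripts)

    def classify(
        self, key: VariantKey, upstream_window: int = 5000
    ) -> tuple[str, str | None]:
        return classify_genomic_context(key, self, upstream_window)


def classify_genomic_context(
    key: VariantKey,
    gene_model: GeneModel,
    upstream_window: int = 5000,
) -> tuple[str, str | None]:
    """Classify a variant position: exonic > intron > upstream_gene > intergenic.

    Exonic: within any exon.  Intron: within a transcript span but outside
    its exons.  Upstream: within ``upstream_window`` bp 5' of a transcript
    start, strand-aware.  Positions on chromosomes absent from the gene
    model are intergenic (with a warning).
    """
    transcripts = gene_model._by_chrom.get(key.chrom)
    if transcripts is None:
        warnings.warn(
            f"chromosome {key.chrom!r} not in gene model; classifying intergenic",
            stacklevel=2,
        )
        return "intergenic", None
    pos = key.pos
    intron_gene = None
    upstream_gene = None
    for t in transcripts:
        for s, e in t.exons:
            if s <= pos <= e:
                return "exonic", t.gene
        if t.start <= pos <= t.end:
            intron_gene = intron_gene or t.gene
        elif t.strand == "+" and t.start - upstream_window <= pos < t.start:
            upstream_gene = upstream_gene or t.gene
        elif t.strand == "-" and t.end < pos <= t.end + upstream_window:
            upstream_gene = upstream_gene or t.gene
    if intron_gene is not None:
        return "intron", intron_gene
    if upstream_gene is not None:
        return "upstream_gene", upstream_gene
    return "intergenic", None


# ---------------------------------------------------------------------------
# Candidate records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateRecord:
    """One surviving candidate with its reporting annotations."""

    key: VariantKey
    context: str = "intergenic"
    gene: str | None = None
    known_id: str | None = None  # rsID; None means novel
    public_af: float | None = None

    @property
    def novel(self) -> bool:
        return self.known_id is None


def novelty_classification(records: Sequence[CandidateRecord]) -> dict[str, int]:
    """Count candidates absent from the rsID catalogue (novel) vs. known."""
    novel = sum(1 for r in records if r.novel)
    return {"novel": novel, "known": len(records) - novel}


@dataclass
class Cluster:
    """Run of candidates on one chromosome with consecutive gaps <= max_gap."""

    chrom: str
    members: list[CandidateRecord]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.members[-1].key.pos - self.members[0].key.pos


def cluster_candidates(
    records: Sequence[CandidateRecord], max_gap: int = 3_000_000
) -> list[Cluster]:
    """Single-linkage 1-D clustering of candidate positions.

    A new cluster starts when the chromosome changes or the gap to the
    previous position exceeds ``max_gap`` (default 3 Mb).  Clusters are
    returned largest first (ties by position).
    """
    ordered = sorted(records, key=lambda r: (r.key.chrom, r.key.pos))
    clusters: list[Cluster] = []
    for rec in ordered:
        if (
            clusters
            and clusters[-1].chrom == rec.key.chrom
            and rec.key.pos - clusters[-1].members[-1].key.pos <= max_gap
        ):
            clusters[-1].members.append(rec)
        else:
            clusters.append(Cluster(chrom=rec.key.chrom, members=[rec]))
    return sorted(
        clusters, key=lambda c: (-c.size, c.chrom, c.members[0].key.pos)
    )


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------


def load_candidate_table(path: str | Path) -> list[CandidateRecord]:
    """Read a candidate TSV (chrom, pos, ref, alt, type, gene, dbsnp_id, eur_aaf)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "dbsnp_id": str})
    records = []
    for row in df.itertuples(index=False):
        known = getattr(row, "dbsnp_id", None)
        if pd.isna(known) or known in ("-", ""):
            known = None
        af = getattr(row, "eur_aaf", None)
        if af is not None and (pd.isna(af) or af == "-"):
            af = None
        gene = getattr(row, "gene", None)
        if pd.isna(gene) or gene in ("-", "None", ""):
            gene = None
        records.append(
            CandidateRecord(
                key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
                context=row.type,
                gene=gene,
                known_id=known,
                public_af=None if af is None else float(af),
            )
        )
    return records


def load_packaged_candidates() -> list[CandidateRecord]:
    """The packaged CRC1 candidate table: the 26 variants that survived the
    full filtering analysis of a Swedish autosomal-dominant colorectal-cancer
    family with 2 phenocopies and 1 control-cohort carrier allowed."""
    with importlib_resources.as_file(
        importlib_resources.files("famsieve.data") / "crc1_candidates.tsv"
    ) as p:
        return load_candidate_table(p)


def candidate_summary(records: Sequence[CandidateRecord], max_gap: int = 3_000_000) -> dict:
    clusters = cluster_candidates(records, max_gap)
    contexts: dict[str, int] = {c: 0 for c in CONTEXTS}
    for r in records:
        contexts[r.context] = contexts.get(r.context, 0) + 1
    return {
        "n_candidates": len(records),
        "novelty": novelty_classification(records),
        "contexts": contexts,
        "n_clusters": len(clusters),
        "largest_cluster_size": clusters[0].size if clusters else 0,
        "largest_cluster_chrom": clusters[0].chrom if clusters else None,
        "largest_cluster_span_bp": clusters[0].span if clusters else 0,
    }
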