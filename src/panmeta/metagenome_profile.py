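"""Metagenome-to-reference profiling.

Two views of how well reference strains are represented in metagenome
samples:

* :func:`joint_cluster_profile` clusters reference and sample proteins
  together and reports, per strain and sample, the percentage of the
  strain's genes that fall in clusters also containing a gene of the
  sample, plus the mean identity over those clustered pairs;
* :func:`summarize_contig_hits` consumes precomputed 12-column tabular
  alignment hits of assembled contigs against reference genomes and
  reports, per genome, the retained best-hit count, the merged-interval
  covered fraction and the mean identity of retained hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from panmeta.clustering import ClusterParams, greedy_cluster, pairwise_identity
from panmeta.seqio import GeneRecord, HitRecord, ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageProfile",
    "ContigHomologySummary",
    "joint_cluster_profile",
    "summarize_contig_hits",
]


@dataclass
class CoverageProfile:
    """Strain x sample coverage ratios (percent) and mean identities.

    ``coverage.values[s, m]`` is the percentage of strain ``s`` genes lying
    in clusters that contain at least one gene of sample ``m``;
    ``mean_identity.values[s, m]`` averages, over those strain genes, the
    best pairwise identity (percent) to a sample gene sharing the cluster
    (NaN when no gene is clustered).
    """

    coverage: ProfileMatrix
    mean_identity: ProfileMatrix


def joint_cluster_profile(
    reference_proteomes: Mapping[str, Sequence[GeneRecord]],
    sample_proteins: Mapping[str, Sequence[GeneRecord]],
    params: ClusterParams,
) -> CoverageProfile:
    """Cluster references and samples jointly; profile per-strain coverage.

    All records are pooled and clustered once with
    :func:`~panmeta.clustering.greedy_cluster`.  For strain ``s`` and
    sample ``m``::

        r_s(m) = 100 * |{g in s : cluster(g) contains a gene of m}| / |s|

    Mean identity pairs each such strain gene with the sample gene of
    maximum pairwise identity within its cluster.
    """
    strains = list(reference_proteomes)
    samples = list(sample_proteins)
    for strain in strains:
        if not reference_proteomes[strain]:
            raise ValueError(f"empty reference proteome for strain {strain!r}")

    pooled: list[GeneRecord] = []
    for strain in strains:
        pooled.extend(reference_proteomes[strain])
    for sample in samples:
        pooled.extend(sample_proteins[sample])

    cluster_set = greedy_cluster(pooled, params)

    source_of = {rec.id: rec.source for rec in pooled}
    seq_of = {rec.id: rec.sequence for rec in pooled}

    # cluster index -> sample -> member gene ids of that sample
    sample_members: list[dict[str, list[str]]] = [
        {} for _ in range(len(cluster_set))
    ]
    for idx, cluster in enumerate(cluster_set.clusters):
        for member in cluster.members:
            src = source_of[member.gene_id]
            if src in sample_proteins:
                sample_members[idx].setdefault(src, []).append(member.gene_id)

    cov = np.zeros((len(strains), len(samples)))
    ident = np.full((len(strains), len(samples)), np.nan)
    for si, strain in enumerate(strains):
        genes = reference_proteomes[strain]
        for mi, sample in enumerate(samples):
            hit_idents: list[float] = []
            for gene in genes:
                cidx = cluster_set.gene_to_cluster[gene.id]
                partners = sample_members[cidx].get(sample)
                if not partners:
                    continue
                best = max(
                    pairwise_identity(gene.sequence, seq_of[p])[0]
                    for p in partners
                )
                hit_idents.append(best)
            cov[si, mi] = 100.0 * len(hit_idents) / len(genes)
            if hit_idents:
                ident[si, mi] = 100.0 * float(np.mean(hit_idents))

    return CoverageProfile(
        coverage=ProfileMatrix(strains, samples, cov),
        mean_identity=ProfileMatrix(strains, samples, ident),
    )


@dataclass(frozen=True)
class ContigHomologySummary:
    """Per-genome summary of retained contig best hits."""

    genome: str
    n_hits: int
    covered_fraction: float   # percent of genome length covered, overlaps merged
    mean_identity: float      # percent, NaN when no hits retained


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    merged = 0
    last_end = 0
    for start, end in sorted(intervals):
        if start > last_end:
            merged += end - start + 1
            last_end = end
        elif end > last_end:
            merged += end - last_end
            last_end = end
    return merged


def summarize_contig_hits(
    hits: Sequence[HitRecord],
    min_identity: float,
    max_evalue: float,
    min_contig_length: int,
    contig_lengths: Mapping[str, int],
    genome_lengths: Mapping[str, int],
) -> dict[str, ContigHomologySummary]:
    """Filter hits, retain per-contig best hits, summarize per genome.

    Filtering keeps contigs of length >= ``min_contig_length`` and hits
    with ``evalue <= max_evalue`` and ``percent_identity >=
    min_identity``.  The best hit of a contig has the lowest evalue (ties:
    highest bitscore, then highest identity, then subject id).  Per genome
    the summary counts retained hits, merges their subject intervals
    (overlap counted once) and averages their identities.
    """
    filtered: list[HitRecord] = []
    for hit in hits:
        if hit.subject_id not in genome_lengths:
            raise ValueError(f"hit references unknown genome {hit.subject_id!r}")
        if hit.query_id not in contig_lengths:
            raise ValueError(f"hit references unknown contig {hit.query_id!r}")
        if contig_lengths[hit.query_id] < min_contig_length:
            continue
        if hit.evalue > max_evalue or hit.percent_identity < min_identity:
            continue
        filtered.append(hit)

    best_by_contig: dict[str, HitRecord] = {}
    for hit in filtered:
        current = best_by_contig.get(hit.query_id)
        key = (hit.evalue, -hit.bitscore, -hit.percent_identity, hit.subject_id)
        if current is None:
            best_by_contig[hit.query_id] = hit
            continue
        cur_key = (
            current.evalue,
            -current.bitscore,
            -current.percent_identity,
            current.subject_id,
        )
        if key < cur_key:
            best_by_contig[hit.query_id] = hit

    per_genome: dict[str, list[HitRecord]] = {g: [] for g in genome_lengths}
    for hit in best_by_contig.values():
        per_genome[hit.subject_id].append(hit)

    summaries: dict[str, ContigHomologySummary] = {}
    for genome, ghits in per_genome.items():
        intervals = [
            tuple(sorted((h.subject_start, h.subject_end))) for h in ghits
        ]
        covered = _merged_length(intervals)
        summaries[genome] = ContigHomologySummary(
            genome=genome,
            n_hits=len(ghits),
            covered_fraction=100.0 * covered / genome_lengths[genome],
            mean_identity=(
                float(np.mean([h.percent_identity for h in ghits]))
                if ghits
                else float("nan")
            ),
        )
    return summaries
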