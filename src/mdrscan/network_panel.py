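"""Per-network SNP panel assembly and k-way model enumeration.

A gene-interaction network is just a named gene list; genes carry
1-based-inclusive genomic intervals.  A panel is the deduplicated,
position-sorted set of post-QC SNPs falling in any of a network's genes.
Networks are analysed independently, so a SNP inside genes of two networks
is tested in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .genotype_io import GenotypeMatrix, VariantRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class NetworkDefinition:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"network {self.name}: duplicate gene symbols")


@dataclass
class SnpPanel:
    network: str
    snp_ids: list[str]
    snp_to_gene: dict[str, list[str]]

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def read_networks(path: str | Path) -> list[NetworkDefinition]:
    """Read ``network<TAB>gene_symbol`` pairs, one per row."""
    nets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, gene = line.rstrip("\n").split("\t")[:2]
        nets.setdefault(name, [])
        if gene not in nets[name]:
            nets[name].append(gene)
    return [NetworkDefinition(n, tuple(g)) for n, g in nets.items()]


def read_intervals(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals: TSV symbol, chrom, start, end (1-based incl.)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sym, chrom, start, end = line.rstrip("\n").split("\t")[:4]
        out.append(GeneInterval(sym, chrom, int(start), int(end)))
    return out


def map_snps_to_genes(
    variants: Sequence[VariantRecord],
    intervals: Sequence[GeneInterval],
    flank_bp: int = 0,
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose flanked interval contains it.

    SNPs landing in no gene are absent from the mapping.
    """
    mapping: dict[str, list[str]] = {}
    for v in variants:
        hits = [
            iv.symbol
            for iv in intervals
            if iv.chrom == v.chrom and iv.start - flank_bp <= v.pos <= iv.end + flank_bp
        ]
        if hits:
            mapping[v.snp_id] = hits
    return mapping


def build_panel(
    network: NetworkDefinition,
    mapping: Mapping[str, list[str]],
    matrix: GenotypeMatrix,
) -> SnpPanel:
    """All post-QC SNPs mapped to any network gene, deduplicated, sorted."""
    gene_set = set(network.genes)
    chosen: dict[str, list[str]] = {}
    for v in matrix.variants:
        genes = [g for g in mapping.get(v.snp_id, []) if g in gene_set]
        if genes:
            chosen[v.snp_id] = genes
    hit_genes = {g for gs in chosen.values() for g in gs}
    for g in gene_set - hit_genes:
        log.info("network %s: gene %s contributes no SNPs", network.name, g)
    order = sorted(
        chosen, key=lambda s: (matrix.variants[matrix.column_index(s)].chrom,
                               matrix.variants[matrix.column_index(s)].pos)
    )
    if not order:
        log.warning("network %s: empty SNP panel", network.name)
    return SnpPanel(network.name, order, {s: chosen[s] for s in order})


def load_reference_panel_sizes() -> dict[str, int]:
    """Synthetic per-network panel sizes bundled with the package.

    A stand-in for the undeposited post-QC panel sizes of the five Wnt
    interactome networks, reconstructed as the unique five-part solution
    consistent with the published two-way and three-way model totals.
    """
    path = Path(__file__).parent / "data" / "synthetic_panel_sizes.tsv"
    out: dict[str, int] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, n = line.split("\t")
        out[name] = int(n)
    return out


def count_combinations(panel_sizes: Iterable[int], k: int) -> int:
    """Sum over panels of C(n_i, k), exact integer arithmetic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sum(comb(n, k) for n in panel_sizes)


def iter_combinations(panel: SnpPanel, k: int) -> Iterator[tuple[str, ...]]:
    """Lexicographic stream of SNP k-tuples over the panel order."""
    if k > panel.size:
        raise ValueError(f"k={k} exceeds panel size {panel.size}")
    return combinations(panel.snp_ids, k)
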