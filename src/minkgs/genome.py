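"""Genome map construction and meiosis.

The genome is a set of autosomal chromosomes carrying point loci on a
genetic map (centimorgans).  Meiosis follows a no-interference model:
the crossover count on each chromosome is Poisson with mean equal to the
map length in Morgans, crossover positions are uniform along the
chromosome, and the starting parental strand is chosen at random.
Recurrent mutation converts a transmitted allele to a uniformly chosen
other allele of that locus with a fixed per-allele probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

# locus classes
CANDIDATE_MARKER = 0  # biallelic, eligible for the marker panel
CANDIDATE_QTL = 1     # 2-4 alleles, eligible as QTL
MARKER = 2            # recruited marker-panel locus
QTL = 3               # recruited trait locus


@dataclass
class GenomeMap:
    """Coordinate backbone for meiosis, trait machinery and LD binning.

    Parameters
    ----------
    chrom_lengths:
        Genetic length of each chromosome in cM.
    locus_chrom, locus_pos:
        Per-locus chromosome index and position (cM within chromosome).
        Loci must be grouped by chromosome and sorted by position.
    locus_class:
        One of ``CANDIDATE_MARKER``, ``CANDIDATE_QTL``, ``MARKER``, ``QTL``.
    n_alleles:
        Allele count per locus (2 for markers, 2-4 for QTL loci).
    """

    chrom_lengths: np.ndarray
    locus_chrom: np.ndarray
    locus_pos: np.ndarray
    locus_class: np.ndarray
    n_alleles: np.ndarray
    # mutation domain: a restricted map remembers the loci of its parent
    # map, so recurrent mutation is drawn over the whole genome and only
    # hits represented loci -- the draw stream is then independent of
    # which panel was recruited
    orig_index: np.ndarray | None = None
    domain_alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.float64)
        self.locus_chrom = np.asarray(self.locus_chrom, dtype=np.int32)
        self.locus_pos = np.asarray(self.locus_pos, dtype=np.float64)
        self.locus_class = np.asarray(self.locus_class, dtype=np.int8)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int8)
        if np.any(np.diff(self.locus_chrom) < 0):
            raise ValueError("loci must be grouped by chromosome in order")
        for c in range(self.n_chromosomes):
            sel = self.locus_chrom == c
            p = self.locus_pos[sel]
            if p.size and (np.any(np.diff(p) < 0) or p.min() < 0
                           or p.max() > self.chrom_lengths[c]):
                raise ValueError(f"positions on chromosome {c} out of order "
                                 "or outside [0, length]")
        if np.any(self.n_alleles < 2) or np.any(self.n_alleles > 4):
            raise ValueError("allele counts must be in 2..4")
        mk = np.isin(self.locus_class, (CANDIDATE_MARKER, MARKER))
        if np.any(self.n_alleles[mk] != 2):
            raise ValueError("markers must be biallelic")
        # locus index range per chromosome, used by the meiosis kernel
        starts = np.searchsorted(self.locus_chrom, np.arange(self.n_chromosomes))
        ends = np.searchsorted(self.locus_chrom,
                               np.arange(self.n_chromosomes), side="right")
        self._chrom_bounds = np.stack([starts, ends], axis=1).astype(np.int64)
        self._pos_morgans = self.locus_pos / 100.0
        if self.orig_index is None:
            self.orig_index = np.arange(self.n_loci)
            self.domain_alleles = self.n_alleles

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.locus_pos)

    @property
    def total_length_cm(self) -> float:
        return float(self.chrom_lengths.sum())

    def subset(self, idx: np.ndarray, new_class: np.ndarray | None = None) -> "GenomeMap":
        """Map restricted to loci ``idx`` (kept in genome order); the
        mutation domain of the parent map is preserved."""
        idx = np.sort(np.asarray(idx))
        cls = self.locus_class[idx] if new_class is None else new_class
        return GenomeMap(self.chrom_lengths, self.locus_chrom[idx],
                         self.locus_pos[idx], cls, self.n_alleles[idx],
                         orig_index=self.orig_index[idx],
                         domain_alleles=self.domain_alleles)


def build_genome_map(n_marker_candidates: int,
                     n_qtl_candidates: int,
                     rng: np.random.Generator,
                     n_chromosomes: int = 14,
                     total_length_cm: float = 1192.0,
                     chrom_lengths: np.ndarray | None = None,
                     qtl_allele_choices: tuple[int, ...] = (2, 3, 4)) -> GenomeMap:
    """Draw a random candidate-locus map.

    Chromosome lengths default to equal shares of the total map length.
    Candidate loci are placed uniformly; QTL candidacy is assigned to a
    random subset whose allele counts are drawn uniformly from
    ``qtl_allele_choices``.
    """
    if chrom_lengths is None:
        chrom_lengths = np.full(n_chromosomes, total_length_cm / n_chromosomes)
    chrom_lengths = np.asarray(chrom_lengths, dtype=np.float64)
    n_loci = n_marker_candidates + n_qtl_candidates
    # allocate loci to chromosomes proportionally to length
    counts = rng.multinomial(n_loci, chrom_lengths / chrom_lengths.sum())
    locus_chrom = np.repeat(np.arange(len(chrom_lengths), dtype=np.int32), counts)
    locus_pos = np.concatenate([
        np.sort(rng.random(k)) * chrom_lengths[c]
        for c, k in enumerate(counts)
    ]) if n_loci else np.empty(0)
    locus_class = np.full(n_loci, CANDIDATE_MARKER, dtype=np.int8)
    qtl_sites = rng.choice(n_loci, size=n_qtl_candidates, replace=False)
    locus_class[qtl_sites] = CANDIDATE_QTL
    n_alleles = np.full(n_loci, 2, dtype=np.int8)
    n_alleles[qtl_sites] = rng.choice(qtl_allele_choices, size=n_qtl_candidates)
    return GenomeMap(chrom_lengths, locus_chrom, locus_pos, locus_class, n_alleles)


def alloc_haplotypes(n: int, n_loci: int) -> tuple[np.ndarray, np.ndarray | None]:
    """Allocate an (n, 2, n_loci) int8 haplotype array, backed by an
    int64 buffer when the locus count allows word-wise meiosis copies."""
    if n_loci % 8 == 0:
        base = np.empty((n, 2, n_loci // 8), np.int64)
        return base.view(np.int8).reshape(n, 2, n_loci), base
    return np.empty((n, 2, n_loci), np.int8), None


def drop_gametes(haps: np.ndarray, parent_idx: np.ndarray, gmap: GenomeMap,
                 rng: np.random.Generator, mutation_rate: float = 0.0,
                 out: np.ndarray | None = None,
                 out_words: np.ndarray | None = None) -> np.ndarray:
    """Produce one gamete per entry of ``parent_idx`` from ``haps``.

    ``haps`` has shape (n_individuals, 2, n_loci); the result has shape
    (len(parent_idx), n_loci).  ``out``/``out_words`` may supply an
    int8 destination and its aliasing int64 view (from
    :func:`alloc_haplotypes`) to avoid a copy on the hot path.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    n_gam = len(parent_idx)
    L = gmap.n_loci
    if haps.shape[2] != L:
        raise ValueError("haplotype length does not match the genome map")
    C = gmap.n_chromosomes
    # parents: word-aliased fast path, or a padded copy
    if L % 8 == 0 and haps.flags["C_CONTIGUOUS"]:
        h8, h64 = haps, haps.view(np.int64)
    else:
        Lp = -(-L // 8) * 8
        h8 = np.zeros((haps.shape[0], 2, Lp), np.int8)
        h8[:, :, :L] = haps
        h64 = h8.view(np.int64)
    direct = out is not None and out_words is not None
    if direct:
        buf8, buf64 = out, out_words
    else:
        buf64 = np.empty((n_gam, h64.shape[2]), np.int64)
        buf8 = buf64.view(np.int8)
    lens_m = gmap.chrom_lengths / 100.0
    start_hap = rng.integers(0, 2, size=(n_gam, C), dtype=np.uint8)
    xo_counts = rng.poisson(lens_m, size=(n_gam, C)).astype(np.int64)
    flat = xo_counts.ravel()
    xo_offsets = (np.cumsum(flat) - flat).reshape(n_gam, C)
    total = int(flat.sum())
    per_event_len = np.repeat(np.tile(lens_m, n_gam), flat)
    xo_pos = rng.random(total) * per_event_len
    _kernels.gametes_kernel(buf8, buf64, h8, h64, parent_idx, start_hap,
                            xo_counts, xo_offsets, xo_pos, gmap._chrom_bounds,
                            gmap._pos_morgans)
    res = buf8 if direct else buf8[:, :L]
    if mutation_rate > 0.0:
        _mutate(res, gmap, mutation_rate, rng)
    if out is not None and not direct:
        out[:] = res
        return out
    return res


def _mutate(gametes: np.ndarray, gmap: GenomeMap, rate: float,
            rng: np.random.Generator) -> None:
    """Recurrent mutation in place: each transmitted allele mutates with
    probability ``rate`` to a uniformly chosen other allele of its locus.

    Events are drawn over the full mutation domain of the map (all loci
    of the ancestral candidate map); events on loci not represented in a
    restricted map are no-ops but still consume the same random draws.
    """
    D = len(gmap.domain_alleles)
    n_cells = gametes.shape[0] * D
    n_mut = rng.binomial(n_cells, rate)
    if n_mut == 0:
        return
    flat = rng.integers(0, n_cells, size=n_mut)
    rows = flat // D
    dloci = flat % D
    na = gmap.domain_alleles[dloci].astype(np.int64)
    offs = rng.integers(0, na - 1)
    oi = gmap.orig_index
    pos = np.clip(np.searchsorted(oi, dloci), 0, len(oi) - 1)
    keep = oi[pos] == dloci
    rows, cols = rows[keep], pos[keep]
    old = gametes[rows, cols].astype(np.int64)
    gametes[rows, cols] = ((old + 1 + offs[keep]) % na[keep]).astype(np.int8)


def simulate_meiosis(parent_haps: np.ndarray, gmap: GenomeMap,
                     rng: np.random.Generator,
                     mutation_rate: float = 0.0) -> np.ndarray:
    """One gamete from a single parent's haplotype pair (2, n_loci)."""
    haps = np.ascontiguousarray(parent_haps, dtype=np.int8)[None, :, :]
    return drop_gametes(haps, np.zeros(1, dtype=np.int64), gmap, rng,
                        mutation_rate=mutation_rate)[0]
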