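"""Oligonucleotide probe design for the two-condition rice array.

Three rules are implemented:

* gene probes: two non-overlapping 60-mers tiled backward from the 3' end of
  the transcript (so partial reverse-transcriptase products still hybridize);
* LTR-retrotransposon probes: one 60-mer per 500 bp window over the full
  element, each probe the central 60-mer of its window;
* locus specificity: a probe is locus specific when its design locus is the
  only place in the genome it hybridizes, where a stable hybrid is any
  ungapped 60-bp window (either strand) within Hamming distance 3.

The specificity scan uses pigeonhole seeding: a 60-mer with at most three
mismatches against a window must share at least one exact quarter (15-mer)
with it, so candidate windows are found by exact 15-mer lookup and verified
by direct Hamming count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ferrex.sequences import gc_fraction, revcomp, validate_dna, wallace_tm

log = logging.getLogger(__name__)

PROBE_LEN = 60
LTR_WINDOW = 500
MAX_MISMATCH = 3  # hybrids with up to 3 mismatches are stable


@dataclass
class Probe:
    """A 60-mer probe targeting a window of one feature.

    ``start``/``end`` are 1-based inclusive coordinates within the target
    feature's own sequence (transcript for genes, full element for TE loci).
    """

    id: str
    seq: str
    feature: str
    start: int
    end: int
    x: int = -1
    y: int = -1
    locus_specific: bool | None = None

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)

    @property
    def tm(self) -> float:
        return wallace_tm(self.seq)


@dataclass
class ProbeLayout:
    """All probes of an array plus their grid placement."""

    probes: list[Probe] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": [p.id for p in self.probes],
                "seq": [p.seq for p in self.probes],
                "feature": [p.feature for p in self.probes],
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "x": [p.x for p in self.probes],
                "y": [p.y for p in self.probes],
                "gc": [p.gc for p in self.probes],
                "tm": [p.tm for p in self.probes],
                "locus_specific": [p.locus_specific for p in self.probes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def feature_map(self) -> dict[str, list[Probe]]:
        out: dict[str, list[Probe]] = {}
        for p in self.probes:
            out.setdefault(p.feature, []).append(p)
        return out

    def assign_grid(self, rows: int, cols: int, rng: np.random.Generator) -> None:
        """Scatter probes over a ``rows`` x ``cols`` grid at random cells.

        Random placement decorrelates any spatial bias from feature identity,
        as on a real synthesized array.
        """
        n = len(self.probes)
        if rows * cols < n:
            raise ValueError(f"grid {rows}x{cols} too small for {n} probes")
        cells = rng.permutation(rows * cols)[:n]
        for probe, cell in zip(self.probes, cells):
            probe.y, probe.x = divmod(int(cell), cols)


def design_gene_probes(
    gene_id: str, seq: str, k: int = 2, probe_len: int = PROBE_LEN
) -> list[Probe]:
    """Design up to ``k`` non-overlapping probes at the 3' end of a gene.

    Probes tile backward from the 3'-most base and are returned in 3' -> 5'
    order.  A gene shorter than ``probe_len`` yields no probes (logged); a
    gene shorter than ``k * probe_len`` yields fewer than ``k``.
    """
    seq = validate_dna(seq)
    n_fit = min(k, len(seq) // probe_len)
    if n_fit == 0:
        log.warning("gene %s (%d bp) too short for any %d-mer probe", gene_id, len(seq), probe_len)
        return []
    probes = []
    for i in range(n_fit):
        end = len(seq) - i * probe_len
        start = end - probe_len + 1
        probes.append(
            Probe(
                id=f"{gene_id}|p{i + 1}",
                seq=seq[start - 1 : end],
                feature=gene_id,
                start=start,
                end=end,
            )
        )
    return probes


def tile_ltr_probes(
    te_id: str, seq: str, window: int = LTR_WINDOW, probe_len: int = PROBE_LEN
) -> list[Probe]:
    """Tile a complete LTR-retrotransposon at one probe per 500-bp window.

    Emits ceil(len / window) probes, each the central ``probe_len``-mer of
    its window; the last window's probe is clipped so it stays inside the
    element.
    """
    seq = validate_dna(seq)
    length = len(seq)
    if length < probe_len:
        raise ValueError(f"element {te_id} ({length} bp) shorter than a probe")
    n = -(-length // window)  # ceiling
    probes = []
    for i in range(n):
        w_start = i * window  # 0-based
        w_end = min(w_start + window, length)
        center = (w_start + w_end) // 2
        start = center - probe_len // 2
        start = max(0, min(start, length - probe_len))
        probes.append(
            Probe(
                id=f"{te_id}|t{i + 1}",
                seq=seq[start : start + probe_len],
                feature=te_id,
                start=start + 1,
                end=start + probe_len,
            )
        )
    return probes


class GenomeIndex:
    """Exact k-mer index of a genome for seeded mismatch search.

    The probe is split into ``60 // seed_len`` disjoint seeds; by the
    pigeonhole principle any window within ``seeds - 1`` mismatches shares at
    least one seed exactly, so seed lookup plus Hamming verification is an
    exact <=3-mismatch search for 15-mer seeds.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = 15):
        self.seed_len = seed_len
        self.genome = {name: validate_dna(s) for name, s in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for pos in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[pos : pos + seed_len], []).append((name, pos))

    def _candidates(self, probe: str) -> set[tuple[str, int]]:
        plen = len(probe)
        cands: set[tuple[str, int]] = set()
        for off in range(0, plen - self.seed_len + 1, self.seed_len):
            seed = probe[off : off + self.seed_len]
            for name, pos in self._index.get(seed, ()):
                w_start = pos - off
                if 0 <= w_start <= len(self.genome[name]) - plen:
                    cands.add((name, w_start))
        return cands

    def search(self, probe: str, max_mismatch: int = MAX_MISMATCH) -> list[tuple[str, int, str, int]]:
        """All genome windows within ``max_mismatch`` of ``probe``, both strands.

        Returns ``(chrom, start_1based_forward, strand, n_mismatch)`` tuples.
        Positions always refer to the forward strand of the genome.
        """
        probe = validate_dna(probe)
        plen = len(probe)
        if (max_mismatch + 1) * self.seed_len > plen:
            raise ValueError("seed length too large to guarantee exact search")
        hits = []
        for strand, query in (("+", probe), ("-", revcomp(probe))):
            for name, w_start in sorted(self._candidates(query)):
                window = self.genome[name][w_start : w_start + plen]
                mm = sum(a != b for a, b in zip(query, window))
                if mm <= max_mismatch:
                    hits.append((name, w_start + 1, strand, mm))
        return sorted(hits)


def specificity_check(
    probe: str,
    genome: Mapping[str, str] | GenomeIndex,
    max_mismatch: int = MAX_MISMATCH,
) -> tuple[bool, list[tuple[str, int, str, int]]]:
    """Locus specificity of one probe against a genome.

    A probe is locus specific iff exactly one window in the genome (counting
    both strands, the design locus included) lies within ``max_mismatch``
    mismatches.  Overlapping self-windows at a nonzero offset count as
    distinct hits.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits = index.search(probe, max_mismatch=max_mismatch)
    return len(hits) == 1, hits


def annotate_specificity(
    layout: ProbeLayout, genome: Mapping[str, str], max_mismatch: int = MAX_MISMATCH
) -> None:
    """Set ``locus_specific`` on every probe of a layout in place."""
    index = GenomeIndex(genome)
    for probe in layout.probes:
        probe.locus_specific, _ = specificity_check(probe.seq, index, max_mismatch)


def filter_probes(
    probes: Iterable[Probe],
    gc_bounds: tuple[float, float] | None = None,
    tm_bounds: tuple[float, float] | None = None,
) -> list[Probe]:
    """Optional GC%/Tm filtering; by default no hard filter is applied."""
    out = []
    for p in probes:
        if gc_bounds is not None and not (gc_bounds[0] <= p.gc <= gc_bounds[1]):
            continue
        if tm_bounds is not None and not (tm_bounds[0] <= p.tm <= tm_bounds[1]):
            continue
        out.append(p)
    return out
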