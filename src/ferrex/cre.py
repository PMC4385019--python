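"""Cis-regulatory element (CRE) scanning and occurrence statistics.

A CRE catalog is a set of IUPAC degenerate consensus strings (ABRE-type
ABA-responsive elements, TATA boxes, GT1 cores, ...).  Each motif is scanned
against promoters (1-kb upstream regions) or LTRs on both strands, counting
overlapping matches.  Significance is assessed at two levels:

* per sequence: exact upper-tail binomial probability of observing at least
  the counted matches given a zero-order background model; a CRE "has a
  significant occurrence" in a sequence when this p <= 0.05;
* per sequence set: a Z score for the pooled occurrence count against its
  binomial expectation, with the normal upper-tail p-value.

Under the zero-order model, a window matches with probability
q = prod_j sum_{b in allowed_j} f_b.  The number of scanned windows is
n = 2(L - w + 1) over both strands, except for motifs whose IUPAC pattern
equals its own reverse complement (e.g. RY, TATA): for those the reverse
scan duplicates the forward scan exactly, so the trial count collapses to
n = L - w + 1 and the doubled raw count is halved.

The empirical alternative to the binomial null -- a frequency-preserving
shuffle null -- is provided as a cross-check (:func:`shuffle_null`).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ferrex.sequences import IUPAC, revcomp, validate_iupac

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class Motif:
    id: str
    consensus: str
    annotation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", validate_iupac(self.consensus))

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def aba(self) -> bool:
        return "ABA" in self.annotation.upper()

    def allowed_sets(self) -> list[frozenset[str]]:
        return [IUPAC[s] for s in self.consensus]

    def is_self_revcomp(self) -> bool:
        """True when the motif's per-position base sets equal those of its
        reverse complement, i.e. both strand scans match identical windows."""
        rc = revcomp(self.consensus)
        return [IUPAC[s] for s in rc] == self.allowed_sets()


def load_catalog(path=None) -> list[Motif]:
    """Load a CRE catalog TSV (columns: id, consensus, annotation).

    With no path, the bundled toy catalog of plant CREs (ABA-responsive
    elements flagged in the annotation column) is loaded.
    """
    if path is None:
        ref = resources.files("ferrex") / "data" / "cre_catalog.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    frame["annotation"] = frame.get("annotation", pd.Series([""] * len(frame))).fillna("")
    motifs = [Motif(r.id, r.consensus, r.annotation) for r in frame.itertuples()]
    if len({m.id for m in motifs}) != len(motifs):
        raise ValueError("motif ids must be unique within a catalog")
    return motifs


def _pattern(consensus: str) -> re.Pattern:
    # motif N matches any base including sequence N; concrete symbols never match N
    parts = []
    for sym in consensus:
        bases = "".join(sorted(IUPAC[sym]))
        parts.append("[" + (bases + "N" if sym == "N" else bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")  # lookahead => overlapping matches


def scan_motif(motif: Motif | str, sequence: str) -> tuple[int, list[tuple[int, str]]]:
    """Count occurrences of an IUPAC motif in a sequence, both strands.

    Overlapping matches are counted.  Returns ``(count, positions)`` where
    each position is ``(start_1based_on_forward_strand, strand)``.
    """
    if isinstance(motif, str):
        motif = Motif("anon", motif)
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    if len(seq) < motif.width:
        return 0, []
    hits: list[tuple[int, str]] = []
    for m in _pattern(motif.consensus).finditer(seq):
        hits.append((m.start() + 1, "+"))
    for m in _pattern(revcomp(motif.consensus)).finditer(seq):
        hits.append((m.start() + 1, "-"))
    hits.sort()
    return len(hits), hits


def match_probability(motif: Motif, background: Mapping[str, float]) -> float:
    """Per-window match probability under the zero-order background model."""
    q = 1.0
    for allowed in motif.allowed_sets():
        q *= sum(background[b] for b in allowed)
    return q


def effective_trials(motif: Motif, length: int) -> int:
    """Number of binomial trials for a motif in a sequence of ``length``."""
    windows = max(length - motif.width + 1, 0)
    return windows if motif.is_self_revcomp() else 2 * windows


def effective_count(motif: Motif, raw_count: int) -> int:
    """Raw both-strand count mapped onto the trial model (self-reverse-
    complement motifs are counted once per physical window)."""
    return raw_count // 2 if motif.is_self_revcomp() else raw_count


def per_sequence_significance(
    count: int, length: int, motif: Motif, background: Mapping[str, float]
) -> float:
    """Exact upper-tail binomial p-value for a both-strand match count."""
    q = match_probability(motif, background)
    n = effective_trials(motif, length)
    c = effective_count(motif, count)
    if c == 0 or n == 0:
        return 1.0
    if q == 0.0:
        raise ValueError("observed matches for a motif with zero match probability")
    return float(sps.binom.sf(c - 1, n, q))


def background_from(sequences: Iterable[str]) -> dict[str, float]:
    """Zero-order nucleotide frequencies of a sequence set (N ignored)."""
    counts = {b: 0 for b in "ACGT"}
    for seq in sequences:
        s = seq.upper()
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sequence set")
    return {b: counts[b] / total for b in "ACGT"}


UNIFORM_BACKGROUND = {b: 0.25 for b in "ACGT"}


@dataclass
class OccurrenceMatrix:
    """Per-(sequence, motif) raw both-strand counts and per-sequence
    binomial p-values."""

    counts: pd.DataFrame  # sequences x motifs, raw both-strand counts
    pvalues: pd.DataFrame  # same shape, per-sequence binomial p
    background: dict[str, float]

    def distinct_significant(self, alpha: float = ALPHA) -> pd.Series:
        """Per sequence, the number of distinct CREs with significant
        occurrence (p <= alpha)."""
        return (self.pvalues <= alpha).sum(axis=1)

    def significant_motifs_per_sequence(self, alpha: float = ALPHA) -> pd.DataFrame:
        return self.pvalues <= alpha

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def scan_catalog(
    motifs: Sequence[Motif],
    sequences: Mapping[str, str],
    background: Mapping[str, float] | str = "set",
) -> OccurrenceMatrix:
    """Scan every motif against every sequence.

    ``background`` may be an explicit frequency dict, ``"set"`` (zero-order
    frequencies estimated from the scanned sequences themselves, the
    default) or ``"uniform"``.
    """
    if background == "set":
        bg = background_from(sequences.values())
    elif background == "uniform":
        bg = dict(UNIFORM_BACKGROUND)
    else:
        bg = dict(background)  # type: ignore[arg-type]
    names = list(sequences)
    counts = np.zeros((len(names), len(motifs)), dtype=int)
    pvals = np.ones((len(names), len(motifs)))
    for j, motif in enumerate(motifs):
        for i, name in enumerate(names):
            seq = sequences[name]
            c, _ = scan_motif(motif, seq)
            counts[i, j] = c
            pvals[i, j] = per_sequence_significance(c, len(seq), motif, bg)
    ids = [m.id for m in motifs]
    return OccurrenceMatrix(
        counts=pd.DataFrame(counts, index=names, columns=ids),
        pvalues=pd.DataFrame(pvals, index=names, columns=ids),
        background=bg,
    )


@dataclass
class EnrichmentRecord:
    motif_id: str
    set_label: str
    n_sequences_significant: int
    observed: int
    expected: float
    sd: float
    z: float
    p: float
    flagged: bool = False  # sd == 0: Z undefined


def set_enrichment_z(
    motif: Motif,
    sequences: Mapping[str, str],
    background: Mapping[str, float],
    counts: Mapping[str, int] | None = None,
    set_label: str = "",
    alpha: float = ALPHA,
) -> EnrichmentRecord:
    """Set-level occurrence Z score of one motif over a sequence set.

    Pools the binomial trials of every sequence: N = sum_i n_i, E = N q,
    sd = sqrt(N q (1 - q)), Z = (obs - E) / sd, with the standard normal
    upper tail as p-value.  ``counts`` may supply precomputed raw counts.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    q = match_probability(motif, background)
    big_n = 0
    obs = 0
    n_sig = 0
    for name, seq in sequences.items():
        c = counts[name] if counts is not None else scan_motif(motif, seq)[0]
        big_n += effective_trials(motif, len(seq))
        obs += effective_count(motif, c)
        if per_sequence_significance(c, len(seq), motif, background) <= alpha:
            n_sig += 1
    expected = big_n * q
    sd = float(np.sqrt(big_n * q * (1.0 - q)))
    if sd == 0.0:
        log.warning("motif %s: zero-variance null, Z undefined", motif.id)
        return EnrichmentRecord(motif.id, set_label, n_sig, obs, expected, 0.0,
                                float("nan"), float("nan"), flagged=True)
    z = (obs - expected) / sd
    return EnrichmentRecord(
        motif.id, set_label, n_sig, obs, expected, sd, float(z), float(sps.norm.sf(z))
    )


def enrich_catalog(
    motifs: Sequence[Motif],
    occurrences: OccurrenceMatrix,
    sequences: Mapping[str, str],
    set_label: str = "",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Set-level enrichment records for every motif of a scanned catalog."""
    rows = []
    for motif in motifs:
        rec = set_enrichment_z(
            motif, sequences, occurrences.background,
            counts=occurrences.counts[motif.id].to_dict(),
            set_label=set_label, alpha=alpha,
        )
        rows.append(vars(rec))
    return pd.DataFrame(rows)


@dataclass
class ComplexityGroups:
    """Regulation-complexity classification of up-regulated genes.

    ``counts`` are per-gene numbers of distinct CREs with significant
    occurrence in the 1-kb upstream region; a gene is *complex* when its
    count >= mean + 2 SD over all genes, *simple* when <= mean - 2 SD,
    otherwise *normal* (population SD).
    """

    counts: pd.Series
    labels: pd.Series
    mu: float
    sigma: float

    @property
    def upper(self) -> float:
        return self.mu + 2.0 * self.sigma

    @property
    def lower(self) -> float:
        return self.mu - 2.0 * self.sigma

    def group(self, name: str) -> list[str]:
        return sorted(self.labels.index[self.labels == name])

    def sizes(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum()) for g in ("simple", "normal", "complex")}


def classify_complexity(counts: pd.Series | Mapping[str, int]) -> ComplexityGroups:
    counts = pd.Series(dict(counts) if not isinstance(counts, pd.Series) else counts)
    if len(counts) < 2:
        raise ValueError("need at least two genes to classify")
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=0))
    if sigma == 0.0:
        warnings.warn("zero spread in CRE counts: every gene labeled 'normal'")
        labels = pd.Series("normal", index=counts.index)
        return ComplexityGroups(counts, labels, mu, sigma)
    labels = pd.Series("normal", index=counts.index)
    labels[counts >= mu + 2.0 * sigma] = "complex"
    labels[counts <= mu - 2.0 * sigma] = "simple"
    return ComplexityGroups(counts, labels.sort_index(), mu, sigma)


def venn_partition(
    simple: Iterable[str], normal: Iterable[str], complex_: Iterable[str]
) -> dict[str, int]:
    """Counts of the 7 exclusive regions of the simple/normal/complex 3-set
    Venn diagram of CRE identities."""
    s, n, c = set(simple), set(normal), set(complex_)
    return {
        "simple_only": len(s - n - c),
        "normal_only": len(n - s - c),
        "complex_only": len(c - s - n),
        "simple_normal": len((s & n) - c),
        "simple_complex": len((s & c) - n),
        "normal_complex": len((n & c) - s),
        "all_three": len(s & n & c),
        "union": len(s | n | c),
    }


def group_cre_sets(
    occurrences: OccurrenceMatrix, groups: ComplexityGroups, alpha: float = ALPHA
) -> dict[str, set[str]]:
    """The set of CREs significantly present in at least one member of each
    complexity group."""
    sig = occurrences.significant_motifs_per_sequence(alpha)
    out: dict[str, set[str]] = {}
    for name in ("simple", "normal", "complex"):
        members = groups.group(name)
        sub = sig.loc[sig.index.isin(members)]
        out[name] = set(sub.columns[sub.any(axis=0)]) if len(sub) else set()
    return out


@dataclass
class AbaSummary:
    per_cre: pd.DataFrame  # columns: motif, n_sequences
    n_aba_cres_present: int  # ABA CREs significant in >= 1 sequence
    n_genes_with_any: int
    n_up: int
    percent: int | None  # % of up-regulated genes with >= 1 ABA CRE


def aba_cre_summary(
    occurrences: OccurrenceMatrix, motifs: Sequence[Motif], alpha: float = ALPHA
) -> AbaSummary:
    """Per ABA-responsive CRE, in how many sequences it occurs significantly;
    and how many (what share of) sequences carry at least one such CRE."""
    aba = [m.id for m in motifs if m.aba]
    if not aba:
        raise ValueError("catalog contains no ABA-flagged CREs")
    sig = occurrences.pvalues[aba] <= alpha
    per_cre = pd.DataFrame({"motif": aba, "n_sequences": sig.sum(axis=0).to_numpy()})
    n_up = int(len(occurrences.pvalues))
    n_with = int(sig.any(axis=1).sum())
    percent = int(round(100.0 * n_with / n_up)) if n_up else None
    return AbaSummary(
        per_cre=per_cre,
        n_aba_cres_present=int((per_cre["n_sequences"] > 0).sum()),
        n_genes_with_any=n_with,
        n_up=n_up,
        percent=percent,
    )


def ltr_distribution_chi2(
    significant_ids: Iterable[str], up_ids: Iterable[str], all_ids: Iterable[str]
) -> tuple[float, float, np.ndarray, str]:
    """2x2 chi-square test of a CRE's distribution across LTR sets.

    Rows: significant occurrence vs not; columns: up-regulated vs not.
    No continuity correction by default; if any expected cell is < 1 a
    Fisher exact test is used instead (logged).  Returns
    ``(chi2, p, table, method)``.
    """
    sig = set(significant_ids)
    up = set(up_ids)
    universe = set(all_ids)
    if not up <= universe:
        raise ValueError("up-regulated set must be a subset of the full set")
    not_up = universe - up
    a = len(up & sig)
    b = len(not_up & sig)
    c = len(up - sig)
    d = len(not_up - sig)
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = sps.contingency.expected_freq(table) if table.sum() else table
    if table.sum() == 0 or (expected < 1.0).any():
        log.warning("expected cell < 1: falling back to Fisher's exact test")
        _, p = sps.fisher_exact(table)
        return float("nan"), float(p), table, "fisher"
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table, "chi2"


def shuffle_null(
    motif: Motif,
    sequences: Mapping[str, str],
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Frequency-preserving shuffle null for a motif's pooled count.

    Each shuffle permutes the letters of every sequence independently and
    records the pooled effective count; the returned array is the empirical
    null distribution an analytic Z should agree with.
    """
    rng = rng or np.random.default_rng(0)
    pooled = np.empty(n_shuffles)
    arrays = [np.frombuffer(seq.encode(), dtype="S1") for seq in sequences.values()]
    for k in range(n_shuffles):
        total = 0
        for arr in arrays:
            shuffled = arr[rng.permutation(arr.size)].tobytes().decode()
            total += effective_count(motif, scan_motif(motif, shuffled)[0])
        pooled[k] = total
    return pooled
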