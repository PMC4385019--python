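"""Seeded synthetic-data generator for the whole pipeline.

The generator emulates the study design the downstream stages assume: a
two-condition (control vs iron excess) gridded oligonucleotide array with
three biological replicates per condition, 1.0-kb promoters upstream of each
gene, LTR-retrotransposon loci with 5' and 3' long terminal repeats, planted
differentially expressed features with a known log2 fold change, a smooth
multiplicative spatial bias over the array grid, promoter/LTR sequences with
a configurable background nucleotide composition, planted CRE motifs
enriched in up-regulated features, and a Ct table for qPCR validation
normalized against a reference gene with zero true effect.

Everything is deterministic under the master seed: per-component generators
are spawned from a single :class:`numpy.random.SeedSequence`, so outputs are
byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ferrex.probes import ProbeLayout, design_gene_probes, tile_ltr_probes
from ferrex.sequences import IUPAC, revcomp, validate_iupac, write_fasta

SPACER = 100  # bp of background sequence between features on the chromosome


@dataclass(frozen=True)
class PlantedMotif:
    """A CRE consensus inserted into a class of synthetic sequences.

    ``target_class`` is one of ``up_promoter``, ``all_promoter``, ``up_ltr``,
    ``all_ltr``; ``rate`` is the expected number of inserted copies per
    target sequence.
    """

    motif_id: str
    consensus: str
    target_class: str
    rate: float


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the modeled experiment where it states a value: three
    replicates per condition, 1000-bp promoters, |log2FC| = 2 effects, and a
    DE share of ~5.5% of genes that is strongly up-skewed.  Keeping the DE
    share small also keeps quantile normalization's identical-distributions
    assumption approximately valid, as on the real 385k-probe array.  The
    rest is a realistic scaled-down rice-like scenario: several hundred
    genes, AT-rich intergenic composition, and one ABRE-like ABA-responsive
    motif planted in up-regulated promoters and LTRs.
    """

    seed: int = 0
    n_genes: int = 400
    n_te_loci: int = 100
    n_te_families: int = 20
    promoter_len: int = 1000
    gene_len: int = 900
    ltr_len: int = 350
    te_internal_len: int = 1300
    grid_rows: int = 40
    grid_cols: int = 40
    n_reps_per_condition: int = 3
    frac_up: float = 0.055
    frac_down: float = 0.0025
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    probe_affinity_sd: float = 0.5
    spatial_bias_amplitude: float = 1.0
    spatial_bias_shape: str = "linear"  # or "radial"
    background_freqs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}
    )
    planted_motifs: list[PlantedMotif] = field(
        default_factory=lambda: [
            PlantedMotif("ABRE_SYN", "ACGTGKC", "up_promoter", 2.0),
            PlantedMotif("ABRE_SYN", "ACGTGKC", "up_ltr", 2.0),
        ]
    )
    n_qpcr_genes: int = 17
    n_qpcr_reps: int = 3
    qpcr_noise_sd: float = 0.3
    ct_offset: float = 30.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_te_loci", "n_te_families", "promoter_len",
                     "gene_len", "ltr_len", "te_internal_len", "grid_rows",
                     "grid_cols", "n_reps_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.frac_up and 0 <= self.frac_down and self.frac_up + self.frac_down <= 1):
            raise ValueError("frac_up + frac_down must lie in [0, 1]")
        total = sum(self.background_freqs.get(b, 0.0) for b in "ACGT")
        if abs(total - 1.0) > 1e-9 or set(self.background_freqs) != set("ACGT"):
            raise ValueError("background_freqs must be over A/C/G/T and sum to 1")
        for pm in self.planted_motifs:
            consensus = validate_iupac(pm.consensus)
            if pm.target_class not in ("up_promoter", "all_promoter", "up_ltr", "all_ltr"):
                raise ValueError(f"unknown target class {pm.target_class!r}")
            limit = self.promoter_len if "promoter" in pm.target_class else self.ltr_len
            if len(consensus) >= limit:
                raise ValueError(f"motif {pm.motif_id} longer than its target sequence")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named per-component RNG streams derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("sequences", "layout", "intensities", "qpcr")
        return {name: np.random.default_rng(child) for name, child in zip(names, ss.spawn(len(names)))}


@dataclass
class Feature:
    id: str
    kind: str  # "gene" | "te_locus"
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    promoter: str = ""  # genes: promoter_len bases 5' of the start, gene-strand orientation
    body: str = ""  # genes: transcript; te loci: full element (LTR5+internal+LTR3)
    ltr5: str = ""
    ltr3: str = ""
    family: str = ""  # te loci only


@dataclass
class FeatureSet:
    features: list[Feature]
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique")

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def te_loci(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "te_locus"]

    def by_id(self) -> dict[str, Feature]:
        return {f.id: f for f in self.features}

    def sequence_records(self) -> list[tuple[str, str]]:
        recs = []
        for f in self.features:
            if f.kind == "gene":
                recs.append((f"{f.id}|promoter", f.promoter))
            else:
                recs.append((f"{f.id}|LTR5", f.ltr5))
                recs.append((f"{f.id}|LTR3", f.ltr3))
        return recs

    def to_fasta(self, path) -> None:
        write_fasta(self.sequence_records(), path)

    def to_gff3(self, path) -> None:
        lines = ["##gff-version 3"]
        for name, seq in self.chromosomes.items():
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
        for f in self.features:
            if f.kind == "gene":
                lines.append(
                    f"{f.chrom}\tferrex\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.id}"
                )
            else:
                lines.append(
                    f"{f.chrom}\tferrex\tLTR_retrotransposon\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                    f"ID={f.id};family={f.family}"
                )
                ltr_len = len(f.ltr5)
                lines.append(
                    f"{f.chrom}\tferrex\tlong_terminal_repeat\t{f.start}\t{f.start + ltr_len - 1}"
                    f"\t.\t{f.strand}\t.\tID={f.id}.LTR5;Parent={f.id}"
                )
                lines.append(
                    f"{f.chrom}\tferrex\tlong_terminal_repeat\t{f.end - len(f.ltr3) + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t.\tID={f.id}.LTR3;Parent={f.id}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class TruthTable:
    """Ground truth of the simulation: per-feature DE status and effect,
    plus per-(motif, class) planted insertion rates."""

    effects: pd.DataFrame  # columns: feature, kind, family, status, true_log2fc
    motif_rates: pd.DataFrame  # columns: motif, target_class, rate

    def status_of(self, feature_id: str) -> str:
        row = self.effects.loc[self.effects["feature"] == feature_id]
        return str(row["status"].iloc[0])

    def to_tsv(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int, freqs: dict[str, float]) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([freqs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=length, p=p))


def _realize_motif(rng: np.random.Generator, consensus: str, freqs: dict[str, float]) -> str:
    """Sample a concrete DNA word from an IUPAC consensus, weighting each
    allowed base by the (renormalized) background frequency."""
    out = []
    for sym in consensus:
        allowed = sorted(IUPAC[sym])
        w = np.array([freqs[b] for b in allowed])
        out.append(rng.choice(allowed, p=w / w.sum()))
    return "".join(out)


def _n_copies(rng: np.random.Generator, rate: float) -> int:
    """Integer copy count with expectation exactly ``rate``."""
    base = int(np.floor(rate))
    frac = rate - base
    return base + (1 if rng.random() < frac else 0)


def _insert_motifs(
    rng: np.random.Generator, seq: str, words: list[str]
) -> str:
    """Insert each word at a uniform position, never overlapping a
    previously inserted copy; insertions overwrite background bases."""
    occupied: list[tuple[int, int]] = []
    chars = list(seq)
    for word in words:
        w = len(word)
        for _ in range(200):  # rejection sampling over non-overlapping starts
            start = int(rng.integers(0, len(seq) - w + 1))
            if all(start + w <= s or start >= e for s, e in occupied):
                break
        else:  # pragma: no cover - pathological saturation
            raise RuntimeError("could not place motif without overlap")
        chars[start : start + w] = word
        occupied.append((start, start + w))
    return "".join(chars)


def _assign_status(n: int, frac_up: float, frac_down: float) -> list[str]:
    """Deterministic status assignment: exact counts, not sampled."""
    n_up = int(round(frac_up * n))
    n_down = int(round(frac_down * n))
    if n_up + n_down > n:
        raise ValueError("frac_up + frac_down too large for feature count")
    return ["up"] * n_up + ["down"] * n_down + ["null"] * (n - n_up - n_down)


def generate_features(config: SimulationConfig) -> tuple[FeatureSet, TruthTable]:
    """Generate the synthetic chromosome, features, sequences and ground truth.

    Up/down statuses are assigned (exact proportions), not sampled.  Null
    sequences are i.i.d. draws from ``background_freqs``; planted motifs are
    inserted into their target class at the configured per-sequence rate.
    """
    rng = config.streams()["sequences"]
    freqs = config.background_freqs

    gene_status = _assign_status(config.n_genes, config.frac_up, config.frac_down)
    te_status = _assign_status(config.n_te_loci, config.frac_up, config.frac_down)

    def planted_words(kind_class: str, status: str) -> list[str]:
        words = []
        for pm in config.planted_motifs:
            applies = pm.target_class == f"all_{kind_class}" or (
                status == "up" and pm.target_class == f"up_{kind_class}"
            )
            if applies:
                words.extend(
                    _realize_motif(rng, pm.consensus, freqs)
                    for _ in range(_n_copies(rng, pm.rate))
                )
        return words

    features: list[Feature] = []
    chrom_parts: list[str] = []
    cursor = 0  # 0-based length so far

    def append(part: str) -> tuple[int, int]:
        nonlocal cursor
        chrom_parts.append(part)
        start = cursor + 1
        cursor += len(part)
        return start, cursor

    strands = rng.choice(["+", "-"], size=config.n_genes + config.n_te_loci)

    for i, status in enumerate(gene_status):
        gid = f"gene{i + 1:04d}"
        strand = str(strands[i])
        promoter = _random_seq(rng, config.promoter_len, freqs)
        promoter = _insert_motifs(rng, promoter, planted_words("promoter", status))
        body = _random_seq(rng, config.gene_len, freqs)
        append(_random_seq(rng, SPACER, freqs))
        if strand == "+":
            append(promoter)
            start, end = append(body)
        else:
            # minus strand: body first on the chromosome, promoter after it
            start, end = append(revcomp(body))
            append(revcomp(promoter))
        features.append(
            Feature(gid, "gene", "chr1", start, end, strand, promoter=promoter, body=body)
        )

    for j, status in enumerate(te_status):
        tid = f"te{j + 1:04d}"
        strand = str(strands[config.n_genes + j])
        family = f"fam{(j % config.n_te_families) + 1:02d}"
        ltr5 = _insert_motifs(
            rng, _random_seq(rng, config.ltr_len, freqs), planted_words("ltr", status)
        )
        ltr3 = _insert_motifs(
            rng, _random_seq(rng, config.ltr_len, freqs), planted_words("ltr", status)
        )
        internal = _random_seq(rng, config.te_internal_len, freqs)
        element = ltr5 + internal + ltr3
        append(_random_seq(rng, SPACER, freqs))
        if strand == "+":
            start, end = append(element)
        else:
            start, end = append(revcomp(element))
        features.append(
            Feature(
                tid, "te_locus", "chr1", start, end, strand,
                body=element, ltr5=ltr5, ltr3=ltr3, family=family,
            )
        )

    append(_random_seq(rng, SPACER, freqs))
    feature_set = FeatureSet(features, {"chr1": "".join(chrom_parts)})

    effect = {"up": config.effect_log2fc, "down": -config.effect_log2fc, "null": 0.0}
    effects = pd.DataFrame(
        {
            "feature": [f.id for f in features],
            "kind": [f.kind for f in features],
            "family": [f.family for f in features],
            "status": gene_status + te_status,
            "true_log2fc": [effect[s] for s in gene_status + te_status],
        }
    )
    motif_rates = pd.DataFrame(
        [
            {"motif": pm.motif_id, "target_class": pm.target_class, "rate": pm.rate}
            for pm in config.planted_motifs
        ]
    )
    return feature_set, TruthTable(effects, motif_rates)


def build_layout(features: FeatureSet, config: SimulationConfig) -> ProbeLayout:
    """Design probes for every feature and place them on the array grid."""
    layout = ProbeLayout()
    for f in features.genes():
        layout.probes.extend(design_gene_probes(f.id, f.body))
    for f in features.te_loci():
        layout.probes.extend(tile_ltr_probes(f.id, f.body))
    layout.assign_grid(config.grid_rows, config.grid_cols, config.streams()["layout"])
    return layout


def bias_surface(x: np.ndarray, y: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Smooth spatial bias b(x, y) in log2 units, peak-to-peak equal to
    ``spatial_bias_amplitude``."""
    cols = max(config.grid_cols - 1, 1)
    rows = max(config.grid_rows - 1, 1)
    u = x / cols - 0.5
    v = y / rows - 0.5
    amp = config.spatial_bias_amplitude
    if config.spatial_bias_shape == "linear":
        return amp * (u + v) / 2.0
    if config.spatial_bias_shape == "radial":
        r = np.sqrt(u**2 + v**2)
        return amp * (r / np.sqrt(0.5) - 0.5)
    raise ValueError(f"unknown bias shape {config.spatial_bias_shape!r}")


def generate_intensities(
    features: FeatureSet, layout: ProbeLayout, truth: TruthTable, config: SimulationConfig
):
    """Simulate the probe x sample fluorescence matrix.

    log2 intensity = feature baseline + probe affinity + condition effect
    (from the truth table) + spatial bias b(x, y) + N(0, noise_sd); exported
    on the linear (2^x) scale so the pipeline's log transform is exercised.
    """
    from ferrex.microarray import IntensityMatrix

    rng = config.streams()["intensities"]
    effect = dict(zip(truth.effects["feature"], truth.effects["true_log2fc"]))
    baselines = {f.id: 10.0 + rng.normal(0.0, 1.0) for f in features.features}
    n_reps = config.n_reps_per_condition
    samples = [f"control_{r + 1}" for r in range(n_reps)] + [f"iron_{r + 1}" for r in range(n_reps)]
    conditions = {s: ("iron" if s.startswith("iron") else "control") for s in samples}

    x = np.array([p.x for p in layout.probes], dtype=float)
    y = np.array([p.y for p in layout.probes], dtype=float)
    bias = bias_surface(x, y, config)
    affinity = rng.normal(0.0, config.probe_affinity_sd, size=len(layout.probes))

    base = np.array([baselines[p.feature] for p in layout.probes]) + affinity + bias
    eff = np.array([effect[p.feature] for p in layout.probes])

    data = {}
    for s in samples:
        log2v = base + (eff if conditions[s] == "iron" else 0.0)
        if config.noise_sd > 0:
            log2v = log2v + rng.normal(0.0, config.noise_sd, size=len(layout.probes))
        data[s] = np.exp2(log2v)

    frame = pd.DataFrame(
        {
            "probe": [p.id for p in layout.probes],
            "x": [p.x for p in layout.probes],
            "y": [p.y for p in layout.probes],
            "feature": [p.feature for p in layout.probes],
            **data,
        }
    )
    return IntensityMatrix(frame, conditions)


def generate_qpcr(
    features: FeatureSet, truth: TruthTable, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate a Ct table for qPCR validation.

    Ct = ct_offset - log2(expression) + noise.  The designated reference
    gene (the first null gene, the stand-in for the housekeeping
    normalizer) has zero true effect, so its expected delta-Ct between
    conditions is 0.
    """
    rng = config.streams()["qpcr"]
    gene_truth = truth.effects[truth.effects["kind"] == "gene"]
    null_genes = gene_truth.loc[gene_truth["status"] == "null", "feature"].tolist()
    if not null_genes:
        raise ValueError("no null gene available as qPCR reference")
    reference = null_genes[0]

    up = gene_truth.loc[gene_truth["status"] == "up", "feature"].tolist()
    down = gene_truth.loc[gene_truth["status"] == "down", "feature"].tolist()
    n_down = min(len(down), max(1, config.n_qpcr_genes // 6))
    n_up = min(len(up), config.n_qpcr_genes - n_down)
    targets = up[:n_up] + down[:n_down]
    extra = [g for g in null_genes[1:] if len(targets) < config.n_qpcr_genes]
    targets += extra[: config.n_qpcr_genes - len(targets)]

    effect = dict(zip(gene_truth["feature"], gene_truth["true_log2fc"]))
    base_expr = {g: 5.0 + rng.normal(0.0, 1.0) for g in targets + [reference]}

    rows = []
    for gene in targets + [reference]:
        for condition in ("control", "iron"):
            expr = base_expr[gene] + (effect[gene] if condition == "iron" else 0.0)
            ref_expr = base_expr[reference]
            for rep in range(1, config.n_qpcr_reps + 1):
                noise_t = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
                noise_r = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": config.ct_offset - expr + noise_t,
                        "ct_reference": config.ct_offset - ref_expr + noise_r,
                        "is_reference": gene == reference,
                    }
                )
    return pd.DataFrame(rows)


def write_outputs(
    outdir,
    config: SimulationConfig,
    features: FeatureSet,
    truth: TruthTable,
    layout: ProbeLayout,
    intensities,
    qpcr_table: pd.DataFrame,
) -> None:
    """Write the full synthetic dataset as FASTA/GFF3/TSV plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.to_fasta(outdir / "features.fa")
    features.to_gff3(outdir / "features.gff3")
    write_fasta(features.chromosomes, outdir / "genome.fa")
    layout.to_tsv(outdir / "probes.tsv")
    intensities.to_tsv(outdir / "intensities.tsv")
    qpcr_table.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    truth.to_tsv(outdir / "truth.tsv")
    cfg = asdict(config)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
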