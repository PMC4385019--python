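"""Reported summary values from the motivating rice iron-excess microarray
experiment, used as worked-example inputs.

These are dataset-level numbers as printed in the study's summary tables:
differential-expression counts, ABA-CRE gene counts, LTR-retrotransposon
locus/family counts, leaf micronutrient means, and the per-gene microarray
log2FC vs RT-qPCR log2 RQ validation pairs.  They serve as inputs to the
package's summary arithmetic (percentages, fold ratios, correlations); the
package never asserts them as outputs of its own pipeline.
"""

from __future__ import annotations

#: Differentially expressed genes under iron excess (|log2FC| >= 1, adjusted p <= 0.05).
DE_GENES = {"n_up": 2457, "n_down": 68}

#: Up-regulated genes whose 1-kb upstream region carries >= 1 significantly
#: occurring ABA-responsive CRE, out of all up-regulated genes.
ABA_GENES = {"n_with_aba_cre": 665, "n_up": 2457}

#: Complete LTR-retrotransposon loci and families responding to the stress.
TE_LOCI = {"n_de": 1344, "n_total": 3623}
TE_FAMILIES = {"n_de": 158, "n_total": 369}

#: Leaf micronutrient content means (mg/kg), three replicates per condition.
MICRONUTRIENT_MEANS = {
    "manganese": {"control": 500.50, "iron_excess": 527.87},
    "copper": {"control": 27.72, "iron_excess": 26.38},
    "zinc": {"control": 91.68, "iron_excess": 105.04},
    "iron": {"control": 795.75, "iron_excess": 1927.12},
}

#: Microarray log2FC vs RT-qPCR log2 RQ validation pairs (17 assays; one
#: locus was assayed twice with different RQ outcomes, and the GAPDH
#: reference gene is not part of the pairs).
QPCR_VALIDATION_PAIRS: list[tuple[str, float, float]] = [
    ("Os02g0121700", 2.14, 2.3),
    ("Os02g0594800", 2.48, 3.0),
    ("Os02g0740700", 1.68, 2.5),
    ("Os05g0162000", 2.25, 1.5),
    ("Os06g0257450", 2.26, 3.7),
    ("Os08g0467400", 1.87, 0.8),
    ("Os08g0508000", 2.58, 2.0),
    ("Os12g0601800", 1.67, 1.2),
    ("Os06g0141200", -2.54, -2.0),
    ("Os05g0506000", -1.02, -1.8),
    ("Os10g0521900", -1.21, -1.6),
    ("Os06g0649000", 1.41, 2.5),
    ("Os12g0567800", 2.01, 1.2),
    ("Os12g0567800", 2.01, 0.5),
    ("Os03g0288000", 1.12, 2.0),
    ("Os05g0399300", 3.29, 3.0),
    ("Os12g0571000", 2.43, 2.5),
]
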