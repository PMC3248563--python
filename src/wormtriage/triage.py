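"""The multi-stage triage tree that reduces a genome-wide screen to a core
set of proteostasis modifiers.

Stage order (each stage consumes the survivors of the previous one):

1. ``stage_q35``            — genome-wide suppression calls on the threshold
                              polyQ reporter (positives + strong subset);
2. ``stage_q24_filter``     — remove artifacts flagged in the soluble-reporter
                              counter-screen (phenotypes unrelated to
                              aggregation);
3. ``stage_q37_classify``   — partition survivors into Class A (also suppress
                              the longer-repeat reporter) and Class B;
4. ``stage_sod1``           — record which Class A genes also suppress mutant
                              SOD1 aggregation;
5. ``stage_wt_motility_filter``  — drop genes that alter wild-type motility on
                              their own (t-test on per-track BLPS);
6. ``stage_q35_motility_classes`` — classify the remainder by their effect on
                              polyQ-animal motility (suppress / no change /
                              enhance toxicity); the suppressor class is the
                              toxicity-suppressor set;
7. ``stage_ts_rescue``      — genes rescuing >= 1 of 4 temperature-sensitive
                              metastable-protein strains (>= 40% relative
                              reduction of the mutant phenotype, significant
                              by a two-proportion test) form the core set.

``run_triage`` executes the tree, asserts the set-algebra invariants, and
returns a :class:`TriageResult` with the per-stage counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    IncompleteRecordError,
    PoolingRequiredError,
    UndefinedReductionError,
)
from .foci import (
    Q35_RULE,
    Q37_RULE,
    SOD1_RULE,
    SuppressionCall,
    SuppressionRule,
    suppression_call,
)
from .stats import round_half_away, student_t_test, two_proportion_z_test

__all__ = [
    "FUNCTIONAL_CLASSES",
    "TS_STRAINS",
    "TsOutcome",
    "GeneRecord",
    "ScreenDataset",
    "TriageConfig",
    "TriageResult",
    "compute_calls",
    "stage_q35",
    "stage_q24_filter",
    "stage_q37_classify",
    "stage_sod1",
    "stage_wt_motility_filter",
    "stage_q35_motility_classes",
    "stage_ts_rescue",
    "functional_class_tally",
    "enrichment_chisq",
    "run_triage",
]

#: Fixed functional-annotation vocabulary of the screen.
FUNCTIONAL_CLASSES = (
    "cell cycle/DNA",
    "cell structure/transport",
    "energy/metabolism",
    "protein folding/transport",
    "protein synthesis",
    "RNA synthesis/processing",
    "signaling",
    "unknown",
)

#: The four temperature-sensitive folding-sensor strains (mutant alleles of
#: paramyosin, the myosin chaperone, myosin heavy chain, and perlecan).
TS_STRAINS = ("unc-15", "unc-45", "unc-54", "unc-52")

MOTILITY_CLASSES = ("suppress", "no_change", "enhance")


@dataclass(frozen=True)
class TsOutcome:
    """Phenotype penetrance of one TS strain under one RNAi condition."""

    strain: str
    pct_phenotype_treated: float
    pct_phenotype_control: float
    n_animals: int

    def __post_init__(self):
        if self.strain not in TS_STRAINS:
            raise ValueError(f"unknown TS strain {self.strain!r}")
        for pct in (self.pct_phenotype_treated, self.pct_phenotype_control):
            if not 0 <= pct <= 100:
                raise ValueError("phenotype percentages must be in [0, 100]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class GeneRecord:
    """Everything the triage tree knows about one gene.

    Raw per-animal foci-count arrays and per-track BLPS samples may be given
    instead of (or alongside) pre-computed calls; :func:`compute_calls` fills
    the calls from the raw counts.
    """

    gene_id: str
    functional_class: str = "unknown"
    q35_counts: np.ndarray | None = None
    q37_counts: np.ndarray | None = None
    sod1_counts: np.ndarray | None = None
    q35_call: SuppressionCall | None = None
    q37_call: SuppressionCall | None = None
    sod1_call: SuppressionCall | None = None
    q24_artifact: bool = False
    wt_blps: np.ndarray | None = None
    q35_blps: np.ndarray | None = None
    ts_outcomes: dict[str, TsOutcome] = field(default_factory=dict)

    def __post_init__(self):
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"functional_class {self.functional_class!r} not in vocabulary"
            )


@dataclass
class ScreenDataset:
    """Gene records plus the shared EV-control measurements."""

    records: list[GeneRecord]
    q35_control_counts: np.ndarray | None = None
    q37_control_counts: np.ndarray | None = None
    sod1_control_counts: np.ndarray | None = None
    wt_control_blps: np.ndarray | None = None
    q35_control_blps: np.ndarray | None = None

    def __post_init__(self):
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_id values must be unique")

    def by_gene(self) -> dict[str, GeneRecord]:
        return {r.gene_id: r for r in self.records}


@dataclass
class TriageConfig:
    """Thresholds of the decision tree, with the screen's defaults.

    ``motility_mode`` selects between a single two-sided alpha for the
    polyQ-motility class assignment (the reference behaviour) and a "legend"
    mode with separate, stricter alphas per direction.
    """

    q35_rule: SuppressionRule = field(default_factory=lambda: Q35_RULE)
    q37_rule: SuppressionRule = field(default_factory=lambda: Q37_RULE)
    sod1_rule: SuppressionRule = field(default_factory=lambda: SOD1_RULE)
    wt_alpha: float = 0.001
    motility_alpha: float = 0.05
    motility_mode: str = "single_alpha"  # or "legend"
    legend_suppress_alpha: float = 0.01
    legend_enhance_alpha: float = 0.001
    ts_min_reduction: float = 0.40
    ts_alpha: float = 0.01
    ts_core_min_strains: int = 1
    run_ts: bool = True


@dataclass
class TriageResult:
    """Per-stage outcome sets of one triage run."""

    q35_positives: set[str]
    q35_strong: set[str]
    excluded_by_q24: set[str]
    class_a: set[str]
    class_b: set[str]
    sod1_common: set[str]
    wt_motility_excluded: set[str]
    motility_classes: dict[str, str]
    toxicity_suppressors: set[str]
    core_modifiers: set[str]
    ts_tallies: dict[str, tuple[int, int]]
    stage_counts: dict[str, int]
    class_percentages: dict[str, int]

    def validate(self) -> None:
        """Assert the set-algebra invariants of the tree."""
        survivors = self.q35_positives - self.excluded_by_q24
        if self.class_a | self.class_b != survivors:
            raise AssertionError("class A/B must partition the Q24 survivors")
        if self.class_a & self.class_b:
            raise AssertionError("class A and B must be disjoint")
        if not self.sod1_common <= self.class_a:
            raise AssertionError("SOD1-common set must lie within class A")
        if not self.wt_motility_excluded <= self.class_a:
            raise AssertionError("wt-motility exclusions must lie within class A")
        if not self.toxicity_suppressors <= self.class_a - self.wt_motility_excluded:
            raise AssertionError(
                "toxicity suppressors must pass the wt-motility filter"
            )
        if not self.core_modifiers <= self.toxicity_suppressors:
            raise AssertionError("core modifiers must be toxicity suppressors")
        if self.class_percentages:
            total = sum(self.class_percentages.values())
            if abs(total - 100) > 1:
                raise AssertionError("class percentages must sum to 100 +/- 1")


def _require(record: GeneRecord, attr: str):
    value = getattr(record, attr)
    if value is None:
        raise IncompleteRecordError(f"gene {record.gene_id!r} lacks {attr}")
    return value


def compute_calls(dataset: ScreenDataset, config: TriageConfig | None = None) -> None:
    """Fill suppression calls from raw per-animal foci counts, in place.

    Calls already present are left untouched; counts without a matching
    control table raise :class:`IncompleteRecordError`.
    """
    config = config or TriageConfig()
    specs = (
        ("q35_counts", "q35_call", dataset.q35_control_counts, config.q35_rule),
        ("q37_counts", "q37_call", dataset.q37_control_counts, config.q37_rule),
        ("sod1_counts", "sod1_call", dataset.sod1_control_counts, config.sod1_rule),
    )
    for record in dataset.records:
        for counts_attr, call_attr, control, rule in specs:
            counts = getattr(record, counts_attr)
            if counts is None or getattr(record, call_attr) is not None:
                continue
            if control is None:
                raise IncompleteRecordError(
                    f"{counts_attr} present but no control counts in dataset"
                )
            setattr(
                record,
                call_attr,
                suppression_call(record.gene_id, counts, control, rule),
            )


def stage_q35(records: Sequence[GeneRecord]) -> tuple[set[str], set[str]]:
    """Genome-screen stage: (positives, strong subset)."""
    positives, strong = set(), set()
    for r in records:
        call = _require(r, "q35_call")
        if call.positive:
            positives.add(r.gene_id)
        if call.strong:
            strong.add(r.gene_id)
    return positives, strong


def stage_q24_filter(
    records: Sequence[GeneRecord], positives: Iterable[str]
) -> set[str]:
    """Soluble-reporter counter-screen: artifact-flagged genes to exclude."""
    positives = set(positives)
    return {r.gene_id for r in records if r.gene_id in positives and r.q24_artifact}


def stage_q37_classify(
    records: Sequence[GeneRecord], survivors: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Partition survivors into Class A (also suppress Q37) and Class B."""
    survivors = set(survivors)
    class_a = set()
    for r in records:
        if r.gene_id not in survivors:
            continue
        call = _require(r, "q37_call")
        if call.positive:
            class_a.add(r.gene_id)
    return class_a, survivors - class_a


def stage_sod1(records: Sequence[GeneRecord], class_a: Iterable[str]) -> set[str]:
    """Class A genes whose RNAi also suppresses mutant SOD1 aggregation."""
    class_a = set(class_a)
    common = set()
    for r in records:
        if r.gene_id not in class_a:
            continue
        call = _require(r, "sod1_call")
        if call.positive:
            common.add(r.gene_id)
    return common


def stage_wt_motility_filter(
    records: Sequence[GeneRecord],
    candidates: Iterable[str],
    control_blps: np.ndarray,
    alpha: float = 0.001,
) -> set[str]:
    """Genes whose knockdown alters wild-type motility on its own.

    Two-sided pooled t-test of the gene's wild-type per-track BLPS sample
    against the wild-type EV control; significance at ``alpha`` excludes the
    gene from the toxicity analysis.
    """
    candidates = set(candidates)
    excluded = set()
    for r in records:
        if r.gene_id not in candidates:
            continue
        sample = _require(r, "wt_blps")
        if student_t_test(sample, control_blps).p_value < alpha:
            excluded.add(r.gene_id)
    return excluded


def stage_q35_motility_classes(
    records: Sequence[GeneRecord],
    survivors: Iterable[str],
    control_blps: np.ndarray,
    alpha: float = 0.05,
    mode: str = "single_alpha",
    legend_suppress_alpha: float = 0.01,
    legend_enhance_alpha: float = 0.001,
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify each survivor's effect on polyQ-animal motility.

    ``suppress`` — significantly faster than the polyQ EV control (toxicity
    suppressed); ``enhance`` — significantly slower; ``no_change`` otherwise.
    The reference mode applies one two-sided ``alpha`` with the direction
    taken from the sign of the mean difference; ``mode="legend"`` instead
    demands p < ``legend_suppress_alpha`` upward and p < ``legend_enhance_alpha``
    downward.  Percentages are rounded half away from zero and returned per
    class.
    """
    survivors = set(survivors)
    classes: dict[str, str] = {}
    for r in records:
        if r.gene_id not in survivors:
            continue
        sample = _require(r, "q35_blps")
        res = student_t_test(sample, control_blps)
        higher = float(np.mean(sample)) > float(np.mean(control_blps))
        if mode == "single_alpha":
            significant = res.p_value < alpha
            up_sig = down_sig = significant
        elif mode == "legend":
            up_sig = res.p_value < legend_suppress_alpha
            down_sig = res.p_value < legend_enhance_alpha
        else:
            raise ValueError(f"unknown motility mode {mode!r}")
        if higher and up_sig:
            classes[r.gene_id] = "suppress"
        elif not higher and down_sig:
            classes[r.gene_id] = "enhance"
        else:
            classes[r.gene_id] = "no_change"
    n = len(classes)
    percentages = {
        label: (
            round_half_away(100.0 * sum(v == label for v in classes.values()) / n)
            if n
            else 0
        )
        for label in MOTILITY_CLASSES
    }
    return classes, percentages


def stage_ts_rescue(
    records: Sequence[GeneRecord],
    toxicity_suppressors: Iterable[str],
    min_reduction: float = 0.40,
    alpha: float = 0.01,
    core_min_strains: int = 1,
) -> tuple[set[str], dict[str, tuple[int, int]]]:
    """Temperature-sensitive rescue stage: the core-modifier set.

    A strain counts as rescued when the relative reduction of the phenotype
    penetrance, ``1 - treated% / control%``, is at least ``min_reduction`` AND
    the treated and control proportions differ by a two-proportion z-test at
    ``alpha``.  A gene joins the core set when it rescues at least
    ``core_min_strains`` of its tested strains.
    """
    tox = set(toxicity_suppressors)
    core = set()
    tallies: dict[str, tuple[int, int]] = {}
    for r in records:
        if r.gene_id not in tox:
            continue
        if not r.ts_outcomes:
            raise IncompleteRecordError(f"gene {r.gene_id!r} lacks TS outcomes")
        rescued = tested = 0
        for outcome in r.ts_outcomes.values():
            tested += 1
            if outcome.pct_phenotype_control == 0:
                raise UndefinedReductionError(
                    f"control phenotype 0% for {r.gene_id!r}/{outcome.strain}"
                )
            reduction = 1.0 - (
                outcome.pct_phenotype_treated / outcome.pct_phenotype_control
            )
            k_treat = int(round(outcome.pct_phenotype_treated / 100 * outcome.n_animals))
            k_ctrl = int(round(outcome.pct_phenotype_control / 100 * outcome.n_animals))
            res = two_proportion_z_test(
                k_treat, outcome.n_animals, k_ctrl, outcome.n_animals
            )
            if reduction >= min_reduction and res.p_value < alpha:
                rescued += 1
        tallies[r.gene_id] = (rescued, tested)
        if rescued >= core_min_strains:
            core.add(r.gene_id)
    return core, tallies


def functional_class_tally(
    records: Sequence[GeneRecord], gene_set: Iterable[str]
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions per functional class over ``gene_set``."""
    gene_set = set(gene_set)
    counts = {c: 0 for c in FUNCTIONAL_CLASSES}
    for r in records:
        if r.gene_id in gene_set:
            counts[r.functional_class] += 1
    total = sum(counts.values())
    fractions = {
        c: (counts[c] / total if total else 0.0) for c in FUNCTIONAL_CLASSES
    }
    return counts, fractions


def enrichment_chisq(
    hit_counts: Mapping[str, int],
    library_fractions: Mapping[str, float],
    total_hits: int | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against library fractions.

    Expected counts are ``library_fraction * total_hits``; classes with an
    expected count below 1 must be pooled by the caller first.
    Returns ``(chi2, df, p)`` with ``df = classes - 1``.
    """
    classes = list(hit_counts)
    obs = np.array([hit_counts[c] for c in classes], dtype=float)
    if total_hits is None:
        total_hits = int(obs.sum())
    exp = np.array(
        [library_fractions[c] * total_hits for c in classes], dtype=float
    )
    if np.any(exp < 1):
        raise PoolingRequiredError(
            "expected count < 1 in some class; merge sparse classes first"
        )
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(classes) - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def run_triage(
    dataset: ScreenDataset, config: TriageConfig | None = None
) -> TriageResult:
    """Execute the full decision tree and return the validated result."""
    config = config or TriageConfig()
    compute_calls(dataset, config)
    records = dataset.records

    q35_positives, q35_strong = stage_q35(records)
    excluded_q24 = stage_q24_filter(records, q35_positives)
    survivors = q35_positives - excluded_q24
    class_a, class_b = stage_q37_classify(records, survivors)
    sod1_common = stage_sod1(records, class_a)
    wt_excluded = stage_wt_motility_filter(
        records, class_a, dataset.wt_control_blps, config.wt_alpha
    )
    motility_survivors = class_a - wt_excluded
    classes, percentages = stage_q35_motility_classes(
        records,
        motility_survivors,
        dataset.q35_control_blps,
        alpha=config.motility_alpha,
        mode=config.motility_mode,
        legend_suppress_alpha=config.legend_suppress_alpha,
        legend_enhance_alpha=config.legend_enhance_alpha,
    )
    toxicity_suppressors = {g for g, c in classes.items() if c == "suppress"}

    core: set[str] = set()
    tallies: dict[str, tuple[int, int]] = {}
    if config.run_ts and any(
        r.ts_outcomes for r in records if r.gene_id in toxicity_suppressors
    ):
        core, tallies = stage_ts_rescue(
            records,
            toxicity_suppressors,
            config.ts_min_reduction,
            config.ts_alpha,
            config.ts_core_min_strains,
        )

    result = TriageResult(
        q35_positives=q35_positives,
        q35_strong=q35_strong,
        excluded_by_q24=excluded_q24,
        class_a=class_a,
        class_b=class_b,
        sod1_common=sod1_common,
        wt_motility_excluded=wt_excluded,
        motility_classes=classes,
        toxicity_suppressors=toxicity_suppressors,
        core_modifiers=core,
        ts_tallies=tallies,
        stage_counts={
            "q35_positives": len(q35_positives),
            "class_a": len(class_a),
            "sod1_common": len(sod1_common),
            "wt_motility_pass": len(motility_survivors),
            "toxicity_suppressors": len(toxicity_suppressors),
            "core_modifiers": len(core),
        },
        class_percentages=percentages,
    )
    result.validate()
    return result
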