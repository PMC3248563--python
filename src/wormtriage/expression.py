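"""Expression-level controls of the screen: qPCR ΔΔCT fold changes and
western-blot band-intensity ratios.

Both quantities answer the same control question — does an RNAi condition
change reporter expression, which would trivially explain a loss of foci?
The comparative-CT method assumes perfect doubling per PCR cycle:

    ΔCT   = mean CT(target) - mean CT(reference gene), per sample
    ΔΔCT  = ΔCT(sample) - ΔCT(calibrator)
    fold  = 2^(-ΔΔCT)

The western readout is the per-replicate reporter/tubulin band-intensity
ratio, expressed as a percentage of the control mean, with a two-sample
Student t-test deciding "unchanged" (p > 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, PairingError
from .stats import student_t_test

__all__ = [
    "CtRecord",
    "BandRecord",
    "BandComparison",
    "ddct_fold_change",
    "band_ratio_pct",
]


@dataclass(frozen=True)
class CtRecord:
    """Replicate CT values for one (gene, sample) pair.

    ``reference_gene`` marks the internal-control gene (e.g. actin) used for
    the within-sample normalization.
    """

    target_gene: str
    sample_label: str
    ct_replicates: tuple[float, ...]
    reference_gene: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "ct_replicates", tuple(float(v) for v in self.ct_replicates)
        )
        if len(self.ct_replicates) < 1:
            raise ValueError("at least one CT replicate required")
        if not all(0 < v < 45 for v in self.ct_replicates):
            raise ValueError("CT values must lie in (0, 45)")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class BandRecord:
    """One biological replicate's band intensities from a western blot."""

    sample_label: str
    yfp_intensity: float
    tubulin_intensity: float
    replicate_id: int = 0

    def __post_init__(self):
        if self.yfp_intensity <= 0 or self.tubulin_intensity <= 0:
            raise ValueError("band intensities must be > 0")

    @property
    def ratio(self) -> float:
        return self.yfp_intensity / self.tubulin_intensity


@dataclass
class BandComparison:
    """Band-ratio comparison of a treated group against its control."""

    pct_of_control: float
    p_value: float | None
    unchanged: bool | None
    treated_ratios: list[float] = field(default_factory=list)
    control_ratios: list[float] = field(default_factory=list)


def ddct_fold_change(
    targets: Sequence[CtRecord],
    reference: Sequence[CtRecord],
    calibrator_label: str,
) -> pd.DataFrame:
    """Comparative-CT relative expression for every (gene, sample) pair.

    Parameters
    ----------
    targets
        CT records of the genes of interest, across samples.
    reference
        CT records of the internal-control gene for the same samples.
    calibrator_label
        Sample whose expression defines fold = 1 (e.g. the EV control).

    Returns a DataFrame with columns ``target_gene, sample_label, delta_ct,
    delta_delta_ct, fold_change``; the calibrator rows have fold 1 exactly.

    Raises
    ------
    PairingError
        If any sample lacks reference-gene CTs, or the calibrator sample is
        missing for a gene.
    """
    ref_means: dict[str, float] = {}
    for rec in reference:
        ref_means.setdefault(rec.sample_label, rec.mean_ct)
    rows = []
    seen_calibrator: dict[str, float] = {}
    for rec in targets:
        if rec.sample_label not in ref_means:
            raise PairingError(
                f"sample {rec.sample_label!r} has no reference-gene CTs"
            )
        delta = rec.mean_ct - ref_means[rec.sample_label]
        rows.append((rec.target_gene, rec.sample_label, delta))
        if rec.sample_label == calibrator_label:
            seen_calibrator[rec.target_gene] = delta
    out = []
    for gene, sample, delta in rows:
        if gene not in seen_calibrator:
            raise PairingError(
                f"calibrator sample {calibrator_label!r} missing for gene {gene!r}"
            )
        ddct = delta - seen_calibrator[gene]
        out.append(
            {
                "target_gene": gene,
                "sample_label": sample,
                "delta_ct": delta,
                "delta_delta_ct": ddct,
                "fold_change": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(out)


def band_ratio_pct(
    treated: Sequence[BandRecord],
    control: Sequence[BandRecord],
    verdict: bool = True,
    welch: bool = False,
    alpha: float = 0.05,
) -> BandComparison:
    """Reporter/tubulin ratios of a treated group as percent of control.

    With ``verdict=True`` (the default) a two-sample Student t-test on the
    per-replicate ratios decides "unchanged" (p > ``alpha``); this requires
    at least two replicates per group (three or more biological replicates is
    the conventional design).
    """
    if not treated or not control:
        raise InsufficientReplicatesError("need >= 1 replicate per group")
    t_ratios = [r.ratio for r in treated]
    c_ratios = [r.ratio for r in control]
    pct = 100.0 * float(np.mean(t_ratios)) / float(np.mean(c_ratios))
    p_value = unchanged = None
    if verdict:
        if len(t_ratios) < 2 or len(c_ratios) < 2:
            raise InsufficientReplicatesError(
                "a verdict requires >= 2 replicates in each group"
            )
        res = student_t_test(t_ratios, c_ratios, welch=welch)
        p_value = res.p_value
        unchanged = p_value > alpha
    return BandComparison(
        pct_of_control=pct,
        p_value=p_value,
        unchanged=unchanged,
        treated_ratios=t_ratios,
        control_ratios=c_ratios,
    )
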