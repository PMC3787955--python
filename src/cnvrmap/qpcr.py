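"""qPCR copy-number validation via relative quantification (2^-ddCT).

dCT is the target-well CT minus the single-copy-control-well CT; ddCT
subtracts the no-CNV calibrator's dCT; RQ = 2^-ddCT, so a two-copy
sample sits near RQ 1 and a one-copy sample near 0.5.  Classification
thresholds default to the published cutoffs: loss strictly below 0.59,
gain at or above 1.59 (both configurable; 100% PCR efficiency assumed
throughout).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from cnvrmap.model import GAIN, GAIN_LOSS, LOSS, QpcrAssay


@dataclass(frozen=True)
class RqThresholds:
    loss_below: float = 0.59
    gain_at_or_above: float = 1.59

    def __post_init__(self) -> None:
        if not (0 < self.loss_below < self.gain_at_or_above):
            raise ValueError(
                "need 0 < loss_below < gain_at_or_above, got "
                f"{self.loss_below} / {self.gain_at_or_above}"
            )


@dataclass(frozen=True)
class RqResult:
    sample_id: str
    cnvr_id: str
    delta_ct_test: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    rq: float
    copy_state: str
    target_ct_sd: float = 0.0
    control_ct_sd: float = 0.0


def _mean_sd(values: Sequence[float], label: str) -> Tuple[float, float]:
    if not values:
        raise ValueError(f"well {label} has zero usable replicates")
    mean = sum(values) / len(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd


def trim_outliers(values: Sequence[float], max_dev: float = 1.0) -> Tuple[float, ...]:
    """Drop replicates more than ``max_dev`` CT from the well median."""
    med = statistics.median(values)
    kept = tuple(v for v in values if abs(v - med) <= max_dev)
    return kept or tuple(values)


def classify_state(rq: float, thresholds: RqThresholds = RqThresholds()) -> str:
    """loss iff rq < loss_below; gain iff rq >= gain_at_or_above; else normal."""
    if not rq > 0:
        raise ValueError(f"rq must be positive, got {rq}")
    if rq < thresholds.loss_below:
        return LOSS
    if rq >= thresholds.gain_at_or_above:
        return GAIN
    return "normal"


def compute_rq(
    assay: QpcrAssay,
    thresholds: RqThresholds = RqThresholds(),
    outlier_trim: bool = False,
) -> RqResult:
    """Relative quantification for one sample against its calibrator.

    Wells aggregate by the mean of their CT replicates (optionally after
    trimming replicates > 1 CT from the well median).
    """
    wells = {
        "target": assay.target_ct,
        "control": assay.control_ct,
        "calibrator_target": assay.calibrator_target_ct,
        "calibrator_control": assay.calibrator_control_ct,
    }
    if outlier_trim:
        wells = {k: trim_outliers(v) for k, v in wells.items()}
    means = {}
    sds = {}
    for name, values in wells.items():
        means[name], sds[name] = _mean_sd(values, name)

    d_test = means["target"] - means["control"]
    d_cal = means["calibrator_target"] - means["calibrator_control"]
    ddct = d_test - d_cal
    rq = 2.0 ** (-ddct)
    return RqResult(
        sample_id=assay.sample_id,
        cnvr_id=assay.cnvr_id,
        delta_ct_test=d_test,
        delta_ct_calibrator=d_cal,
        delta_delta_ct=ddct,
        rq=rq,
        copy_state=classify_state(rq, thresholds),
        target_ct_sd=sds["target"],
        control_ct_sd=sds["control"],
    )


def _observed_type(states: Sequence[str]) -> Optional[str]:
    non_normal = {s for s in states if s != "normal"}
    if not non_normal:
        return None
    if non_normal == {GAIN}:
        return GAIN
    if non_normal == {LOSS}:
        return LOSS
    return GAIN_LOSS


def concordance(
    rq_results: Sequence[RqResult],
    predicted_status: Dict[str, str],
) -> pd.DataFrame:
    """Score qPCR outcomes against predicted CNVR statuses.

    One row per predicted CNVR: ``validated`` is YES iff at least one
    assayed sample is non-normal; ``validated_type`` collapses the
    non-normal states (both -> gain-loss); ``agreement`` says whether
    the observed type matches, extends (observed is a strict superset,
    e.g. gain-loss vs predicted loss), or contradicts the prediction.
    CNVRs with no assays are marked untested and excluded from the
    overall validated fraction (stored in ``df.attrs``).
    """
    by_cnvr: Dict[str, List[RqResult]] = {}
    for r in rq_results:
        by_cnvr.setdefault(r.cnvr_id, []).append(r)

    rows = []
    n_tested = n_validated = 0
    for cnvr_id, predicted in predicted_status.items():
        results = by_cnvr.get(cnvr_id, [])
        if not results:
            rows.append(
                {
                    "cnvr_id": cnvr_id,
                    "n_samples": 0,
                    "validated": "untested",
                    "validated_type": "",
                    "predicted_type": predicted,
                    "agreement": "untested",
                }
            )
            continue
        n_tested += 1
        observed = _observed_type([r.copy_state for r in results])
        validated = observed is not None
        n_validated += validated
        if not validated:
            agreement = "none"
        elif observed == predicted:
            agreement = "match"
        elif observed == GAIN_LOSS or predicted == GAIN_LOSS:
            # one state set strictly contains the other
            agreement = "extends" if observed == GAIN_LOSS else "partial"
        else:
            agreement = "contradicts"
        rows.append(
            {
                "cnvr_id": cnvr_id,
                "n_samples": len(results),
                "validated": "YES" if validated else "NO",
                "validated_type": observed or "-",
                "predicted_type": predicted,
                "agreement": agreement,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_tested"] = n_tested
    df.attrs["n_validated"] = n_validated
    df.attrs["validated_fraction"] = (n_validated / n_tested) if n_tested else float("nan")
    return df
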