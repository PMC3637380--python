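"""Probe-level quality control.

Two filters are applied before any differential calling:

* **detection filter** — a probe is excluded when its detection p-value
  exceeds ``detection_p_max`` (default 0.05, strict >).  Under the default
  ``any_sample`` scope a single failing sample removes the probe; the
  ``all_samples`` scope requires every sample to fail.
* **entity-SD filter** — a probe is excluded when the sample standard
  deviation of its beta values within any single entity exceeds
  ``entity_sd_max`` (default 0.2, strict >), i.e. the probe is not
  measured consistently within at least one entity.

Both inequalities are strict: values exactly at a threshold are retained.
The SD uses the n-1 (sample) denominator by default; ``sd_ddof=0`` selects
the population form.  Entities with fewer than two non-missing values for
a probe contribute no SD and cannot trigger the filter.  When a probe
fails both filters the detection reason takes precedence in the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ValidationError

__all__ = ["QCConfig", "QCReport", "entity_sd", "filter_probes"]

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    detection_p_max: float = 0.05
    entity_sd_max: float = 0.2
    detection_scope: str = "any_sample"  # or "all_samples"
    sd_ddof: int = 1  # 1 = sample SD (n-1); 0 = population SD

    def __post_init__(self) -> None:
        if self.detection_p_max <= 0 or self.entity_sd_max <= 0:
            raise ValidationError("QC thresholds must be positive")
        if self.detection_scope not in ("any_sample", "all_samples"):
            raise ValidationError(
                f"unknown detection scope {self.detection_scope!r}"
            )
        if self.sd_ddof not in (0, 1):
            raise ValidationError("sd_ddof must be 0 or 1")


@dataclass
class QCReport:
    """Accounting of a QC run; reasons sum to the input probe count."""

    n_input_probes: int
    n_removed_detection: int
    n_removed_sd: int
    n_remaining_probes: int
    n_remaining_genes: int
    removal_reason: pd.Series  # probe_id -> {"detection", "sd", "retained"}
    config: QCConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.removal_reason.index,
                "reason": self.removal_reason.to_numpy(),
            }
        )


def entity_sd(values, ddof: int = 1) -> float:
    """Standard deviation of one probe's beta values within one entity.

    Missing values are excluded; with fewer than two non-missing values
    the SD is undefined and NaN is returned (the probe cannot be removed
    on this entity).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=ddof))


def filter_probes(
    matrix: BetaMatrix,
    annotation: pd.DataFrame | None = None,
    config: QCConfig | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Apply detection-p and entity-SD filters; returns (filtered, report).

    Probe order is preserved.  The remaining-gene count requires an
    annotation; without one it is reported as 0.
    """
    config = config or QCConfig()
    beta = matrix.beta
    n_input = len(beta)
    if n_input == 0:
        raise ValidationError("cannot QC an empty matrix")

    # detection filter (skipped when no detection p-values are present)
    if matrix.has_detection:
        exceed = matrix.detection_p.to_numpy(dtype=float) > config.detection_p_max
        exceed = np.where(np.isnan(matrix.detection_p.to_numpy(dtype=float)), False, exceed)
        if config.detection_scope == "any_sample":
            fail_detection = exceed.any(axis=1)
        else:
            fail_detection = exceed.all(axis=1)
    else:
        log.warning("no detection p-values present; detection filter skipped")
        fail_detection = np.zeros(n_input, dtype=bool)

    # within-entity SD filter
    fail_sd = np.zeros(n_input, dtype=bool)
    for ent in matrix.entities:
        samples = matrix.samples_of(ent)
        if len(samples) < 2:
            log.warning(
                "entity %s has <2 samples; SD filter skipped for it", ent
            )
            continue
        sub = beta[samples].to_numpy(dtype=float)
        counts = (~np.isnan(sub)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(sub, axis=1, ddof=config.sd_ddof)
        sd[counts < 2] = np.nan
        # round to 10 decimals so an SD that is exactly the threshold in
        # decimal arithmetic is retained (strict inequality)
        sd = np.round(sd, 10)
        fail_sd |= np.where(np.isnan(sd), False, sd > config.entity_sd_max)

    reason = np.where(
        fail_detection, "detection", np.where(fail_sd, "sd", "retained")
    )
    removal_reason = pd.Series(reason, index=beta.index, name="reason")
    keep = removal_reason == "retained"
    kept_ids = list(beta.index[keep])

    filtered = matrix.subset_probes(kept_ids)
    if annotation is not None:
        genes = annotation.reindex(kept_ids)["gene_symbol"].dropna()
        n_genes = genes.nunique()
    else:
        n_genes = 0

    report = QCReport(
        n_input_probes=n_input,
        n_removed_detection=int((removal_reason == "detection").sum()),
        n_removed_sd=int((removal_reason == "sd").sum()),
        n_remaining_probes=len(kept_ids),
        n_remaining_genes=int(n_genes),
        removal_reason=removal_reason,
        config=config,
    )
    return filtered, report
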